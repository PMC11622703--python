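# Daily dynamic lighting program: illuminance at eye level (lux), correlated
# colour temperature (K) and luminaire drive (%) per clock block. Blocks are
# half-open [start, end); outside the listed blocks the nearest block's
# values are held while the lights are switched on.
- {start: "07:00", end: "08:00", illuminance: 300, cct: 3350, output_pct: 90}
- {start: "08:00", end: "08:30", illuminance: 550, cct: 4000, output_pct: 100}
- {start: "08:30", end: "09:00", illuminance: 550, cct: 5200, output_pct: 100}
- {start: "09:00", end: "14:30", illuminance: 550, cct: 6500, output_pct: 100}
- {start: "14:30", end: "15:00", illuminance: 300, cct: 4200, output_pct: 90}
- {start: "15:00", end: "16:00", illuminance: 260, cct: 3400, output_pct: 90}
- {start: "16:00", end: "18:00", illuminance: 300, cct: 2700, output_pct: 90}
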