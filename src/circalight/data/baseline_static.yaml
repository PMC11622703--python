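# Pre-intervention static lighting: mean illuminance (lux) per area of the
# residents' flats and the shared spaces.
bathrooms: {mean_lux: 99, sd_lux: 49}
bedrooms: {mean_lux: 75, sd_lux: 12}
kitchenette_living: {mean_lux: 59.33, sd_lux: 15.41}
common_areas: {mean_lux: 147, sd_lux: 60.42}
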