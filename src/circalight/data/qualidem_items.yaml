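# Default QUALIDEM item-to-subscale map (37 scored items, 4-point ratings
# 0-3, plus 3 unscored research items on subscale J). Negative-worded items
# carry reverse: true and are re-coded as (max - rating) before summing, so
# larger subscale scores always indicate better quality of life. The map is
# configuration: deployments using a different instrument version supply
# their own file with the same columns.
rating_min: 0
rating_max: 3
items:
  - {item: item_01, subscale: A, reverse: false}
  - {item: item_02, subscale: A, reverse: true}
  - {item: item_03, subscale: A, reverse: false}
  - {item: item_04, subscale: A, reverse: true}
  - {item: item_05, subscale: A, reverse: false}
  - {item: item_06, subscale: A, reverse: true}
  - {item: item_07, subscale: A, reverse: false}
  - {item: item_08, subscale: B, reverse: false}
  - {item: item_09, subscale: B, reverse: false}
  - {item: item_10, subscale: B, reverse: false}
  - {item: item_11, subscale: B, reverse: false}
  - {item: item_12, subscale: B, reverse: false}
  - {item: item_13, subscale: B, reverse: false}
  - {item: item_14, subscale: C, reverse: true}
  - {item: item_15, subscale: C, reverse: true}
  - {item: item_16, subscale: C, reverse: true}
  - {item: item_17, subscale: D, reverse: true}
  - {item: item_18, subscale: D, reverse: true}
  - {item: item_19, subscale: D, reverse: true}
  - {item: item_20, subscale: E, reverse: false}
  - {item: item_21, subscale: E, reverse: true}
  - {item: item_22, subscale: E, reverse: false}
  - {item: item_23, subscale: F, reverse: false}
  - {item: item_24, subscale: F, reverse: false}
  - {item: item_25, subscale: F, reverse: true}
  - {item: item_26, subscale: F, reverse: false}
  - {item: item_27, subscale: F, reverse: true}
  - {item: item_28, subscale: F, reverse: false}
  - {item: item_29, subscale: G, reverse: true}
  - {item: item_30, subscale: G, reverse: true}
  - {item: item_31, subscale: G, reverse: true}
  - {item: item_32, subscale: H, reverse: false}
  - {item: item_33, subscale: H, reverse: false}
  - {item: item_34, subscale: H, reverse: true}
  - {item: item_35, subscale: H, reverse: false}
  - {item: item_36, subscale: I, reverse: false}
  - {item: item_37, subscale: I, reverse: false}
  - {item: item_38, subscale: J, reverse: false}
  - {item: item_39, subscale: J, reverse: false}
  - {item: item_40, subscale: J, reverse: false}
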