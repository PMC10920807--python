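# Bidirectional Reflectance Factor (BRF) data quality flag.
# 8-bit mask; bit 0 is the least significant bit.  The four values observed
# in the data stream are 8 (clear-sky retrieval, daytime), 16 (cloudy
# retrieval, daytime), 24 (no retrieval, daytime), 26 (no retrieval,
# nighttime).  Clear-sky daytime data: use only DQF == 8.
product_id: brf
kind: bitmask
usable_values: [8]
fields:
  - name: land_mask
    bits: [0]
    meanings: {0: "Land", 1: "Water"}
  - name: sza
    bits: [1]
    meanings: {0: "SZA < 67", 1: "SZA >= 67"}
  - name: vza
    bits: [2]
    meanings: {0: "VZA < 70", 1: "VZA >= 70"}
  - name: retrieval_path
    bits: [3, 4]
    meanings: {0: "R1", 1: "R2", 2: "R3", 3: "At least one band has no retrieval"}
  - name: cloud_information
    bits: [5, 6]
    meanings:
      0: "Absolutely clear"
      1: "Probably clear"
      2: "Probably cloudy"
      3: "Absolutely cloudy"
  - name: empty
    bits: [7]
    meanings: {0: "Empty"}
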