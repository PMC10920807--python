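# Land Surface Albedo (LSA) data quality flag.  PROVISIONAL bit layout
# modeled on the companion surface-reflectance flag; edit to match your
# product version.
product_id: lsa
kind: bitmask
provisional: true
usable_values: [0]
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
  - name: retrieval_quality
    bits: [3, 4]
    meanings: {0: "Good", 1: "Degraded", 2: "Climatology fallback", 3: "No retrieval"}
  - name: empty
    bits: [5, 6, 7]
    meanings: {0: "Empty"}
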