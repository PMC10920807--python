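# Cloud and Moisture Imagery (CMI) data quality flag: simple categorical.
product_id: cmi
kind: categorical
usable_values: [0]
levels:
  0: "Good pixel"
  1: "Conditionally usable pixel"
  2: "Out of range pixel"
  3: "No value pixel"
  4: "Focal plane temperature threshold exceeded"
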