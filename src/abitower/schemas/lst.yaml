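# Land Surface Temperature (LST) data quality flag.  PROVISIONAL bit
# layout; edit to match your product version.
product_id: lst
kind: bitmask
provisional: true
usable_values: [0]
fields:
  - name: retrieval
    bits: [0]
    meanings: {0: "Valid retrieval", 1: "Invalid retrieval"}
  - name: cloud
    bits: [1]
    meanings: {0: "Clear", 1: "Cloud obstructed"}
  - name: emissivity_quality
    bits: [2]
    meanings: {0: "Good emissivity input", 1: "Degraded emissivity input"}
  - name: vza
    bits: [3]
    meanings: {0: "VZA in range", 1: "VZA out of range"}
  - name: empty
    bits: [4, 5, 6, 7]
    meanings: {0: "Empty"}
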