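# Aerosol Optical Depth (AOD) data quality flag: simple categorical.
product_id: aod
kind: categorical
usable_values: [0, 1]
levels:
  0: "High quality retrieval"
  1: "Medium quality retrieval"
  2: "Low quality retrieval"
  3: "No retrieval"
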