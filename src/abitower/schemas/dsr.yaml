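# Downward Shortwave Radiation (DSR) data quality flag: simple categorical.
# Observations with DQF == 1 are invalid or degraded and should be removed.
product_id: dsr
kind: categorical
usable_values: [0]
levels:
  0: "Good quality"
  1: "Invalid or degraded observation"
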