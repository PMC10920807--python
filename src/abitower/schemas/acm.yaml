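# Clear Sky Mask (ACM) data quality flag: simple categorical.
product_id: acm
kind: categorical
usable_values: [0]
levels:
  0: "Good quality"
  1: "Invalid due to bad input data"
  2: "Degraded due to missing spatial/temporal context"
  3: "Invalid due to unknown reason"
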