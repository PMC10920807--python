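# Aerosol Detection (ADP) data quality flag.  PROVISIONAL bit layout: the
# operational layout is documented in supplementary product tables not
# reproduced here; edit this file to match your product version.  The
# snow_ice_cloud field ("invalid detection due to snow/ice/clouds") is the
# bit used as a snow-cover proxy when masking the NIRv family.
product_id: adp
kind: bitmask
provisional: true
usable_values: [0]
fields:
  - name: retrieval
    bits: [0]
    meanings: {0: "Valid detection", 1: "Invalid detection"}
  - name: snow_ice_cloud
    bits: [1]
    meanings: {0: "No snow/ice/cloud", 1: "Invalid due to snow_ice_clouds"}
  - name: sza
    bits: [2]
    meanings: {0: "Daytime", 1: "Solar zenith out of range"}
  - name: sun_glint
    bits: [3]
    meanings: {0: "No glint", 1: "Sun glint"}
  - name: empty
    bits: [4, 5, 6, 7]
    meanings: {0: "Empty"}
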