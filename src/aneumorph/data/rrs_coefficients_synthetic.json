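{
 "_comment": "SYNTHETIC illustrative coefficient sets, not a validated clinical model. Sign structure follows the rupture-discriminant literature (risk rises with SR and OSI, falls with NWSS); magnitudes are placeholders. Replace with your own JSON or refit via aneumorph.risk.fit_logistic.",
 "M": {
  "intercept": -4.0,
  "terms": [
   {"feature": "SR", "slope": 2.2, "transform": "identity"}
  ]
 },
 "H": {
  "intercept": 4.0,
  "terms": [
   {"feature": "NWSS", "slope": -1.5, "transform": "log"},
   {"feature": "OSI", "slope": 1.2, "transform": "log"}
  ]
 },
 "C": {
  "intercept": 1.0,
  "terms": [
   {"feature": "SR", "slope": 1.5, "transform": "identity"},
   {"feature": "NWSS", "slope": -1.2, "transform": "log"},
   {"feature": "OSI", "slope": 0.8, "transform": "log"}
  ]
 }
}
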