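{
 "conditions": {
  "n_regions": 100,
  "n_subjects": 50,
  "n_planted": 20,
  "delta_r": 0.5,
  "T": 1200,
  "percentile": 95.0,
  "n_replicates": 10,
  "seed": 20210
 },
 "recalls": [
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0
 ],
 "precisions": [
  0.080972,
  0.081633,
  0.080645,
  0.080645,
  0.080645,
  0.080972,
  0.080645,
  0.080645,
  0.080972,
  0.080972
 ],
 "n_survivors": [
  247,
  245,
  248,
  248,
  248,
  247,
  248,
  248,
  247,
  247
 ]
}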