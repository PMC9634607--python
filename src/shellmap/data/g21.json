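{
 "target_id": "G",
 "n_terms": 21,
 "domain_radius": 10.0,
 "max_error": 0.0002,
 "terms": [
  {
   "mu": 0.0,
   "nu": 10.131,
   "kappa": 0.693
  },
  {
   "mu": 0.339,
   "nu": 3.216,
   "kappa": 0.026
  },
  {
   "mu": 0.873,
   "nu": 4.819,
   "kappa": -0.797
  },
  {
   "mu": 1.439,
   "nu": 3.622,
   "kappa": 0.595
  },
  {
   "mu": 1.979,
   "nu": 3.616,
   "kappa": -0.599
  },
  {
   "mu": 2.462,
   "nu": 4.143,
   "kappa": 0.623
  },
  {
   "mu": 2.953,
   "nu": 3.047,
   "kappa": -0.534
  },
  {
   "mu": 3.492,
   "nu": 2.795,
   "kappa": 0.485
  },
  {
   "mu": 3.971,
   "nu": 2.882,
   "kappa": -0.476
  },
  {
   "mu": 4.471,
   "nu": 2.022,
   "kappa": 0.401
  },
  {
   "mu": 4.995,
   "nu": 1.62,
   "kappa": -0.371
  },
  {
   "mu": 5.504,
   "nu": 2.317,
   "kappa": 0.416
  },
  {
   "mu": 5.98,
   "nu": 2.062,
   "kappa": -0.407
  },
  {
   "mu": 6.49,
   "nu": 1.849,
   "kappa": 0.392
  },
  {
   "mu": 6.989,
   "nu": 1.67,
   "kappa": -0.368
  },
  {
   "mu": 7.49,
   "nu": 1.509,
   "kappa": 0.356
  },
  {
   "mu": 7.991,
   "nu": 1.369,
   "kappa": -0.334
  },
  {
   "mu": 8.493,
   "nu": 1.248,
   "kappa": 0.326
  },
  {
   "mu": 8.995,
   "nu": 1.146,
   "kappa": -0.332
  },
  {
   "mu": 9.494,
   "nu": 1.06,
   "kappa": 0.333
  },
  {
   "mu": 9.978,
   "nu": 0.811,
   "kappa": -0.29
  }
 ],
 "metadata": {
  "convention": "B-additive",
  "note": "reference 21-term decomposition of the 3D interference function over |x| <= 10; coefficients rounded to 3 decimals"
 }
}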