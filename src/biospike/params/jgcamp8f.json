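{
 "name": "jgcamp8f",
 "R_f": 5.000000000000002,
 "n_ca_per_lobe": 2,
 "units": {
  "rates": "1/s",
  "K_a": "uM"
 },
 "lobe_N": {
  "k_off_ca": 4135.574993039339,
  "K_a": 0.5448933482618326,
  "H": 2.9999339531400793,
  "k_on_pep": 2826.2165086218342,
  "k_off_pep": 111.85615229790048
 },
 "lobe_C": {
  "k_off_ca": 1.0084689388893693,
  "K_a": 0.10000000000000002,
  "H": 0.700000000000026,
  "k_on_pep": 5.000965272523018,
  "k_off_pep": 8.936620688180367
 },
 "meta": {
  "fit_loss": 0.00044427442486955976,
  "seed": 7,
  "n_starts": 14,
  "data_version": "slice-statistics calibration targets v1",
  "targets": {
   "rise": 3.1,
   "peak": 0.59,
   "hd1": 41.0,
   "hd10": 123.0,
   "ratio10": 3.0,
   "ppr": 1.0,
   "fast_frac": 0.7
  }
 }
}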