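{
 "name": "jgcamp7f",
 "R_f": 15.194304785216133,
 "n_ca_per_lobe": 2,
 "units": {
  "rates": "1/s",
  "K_a": "uM"
 },
 "lobe_N": {
  "k_off_ca": 312.60070435598055,
  "K_a": 3.924430241624235,
  "H": 2.149724678071405,
  "k_on_pep": 3195.4172201359943,
  "k_off_pep": 75.53298482212477
 },
 "lobe_C": {
  "k_off_ca": 227.93299427406242,
  "K_a": 6.561612687300484,
  "H": 1.4761310833338883,
  "k_on_pep": 611.088572026864,
  "k_off_pep": 268.0857551244065
 },
 "meta": {
  "fit_loss": 7.44416994689266e-21,
  "seed": 7,
  "n_starts": 14,
  "data_version": "slice-statistics calibration targets v1",
  "targets": {
   "rise": 13.7,
   "peak": 0.34,
   "hd1": 77.0,
   "hd10": 126.0,
   "ratio10": null,
   "ppr": 1.9,
   "fast_frac": 0.3
  }
 }
}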