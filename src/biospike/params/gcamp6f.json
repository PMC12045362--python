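{
 "name": "gcamp6f",
 "R_f": 12.10889819083296,
 "n_ca_per_lobe": 2,
 "units": {
  "rates": "1/s",
  "K_a": "uM"
 },
 "lobe_N": {
  "k_off_ca": 20.006318782928005,
  "K_a": 0.48876765570527686,
  "H": 2.999999999997667,
  "k_on_pep": 63.73443641568579,
  "k_off_pep": 95.606532229149
 },
 "lobe_C": {
  "k_off_ca": 1.0009637661087705,
  "K_a": 0.7124521595488648,
  "H": 2.9990871500826426,
  "k_on_pep": 5.009262481667805,
  "k_off_pep": 4.77346174067097
 },
 "meta": {
  "fit_loss": 0.013582549082014131,
  "seed": 7,
  "n_starts": 14,
  "data_version": "slice-statistics calibration targets v1",
  "targets": {
   "rise": 18.1,
   "peak": 0.29,
   "hd1": 78.0,
   "hd10": 130.0,
   "ratio10": 20.0,
   "ppr": 3.1,
   "fast_frac": 0.3
  }
 }
}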