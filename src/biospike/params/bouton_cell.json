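{
 "params": {
  "g_total": 10.0,
  "a_ca": 12.192207065911905,
  "kappa_b": 40.0,
  "pump_vmax": 1230.9114861374635,
  "pump_km": 0.5,
  "store_in_vmax": 20.0,
  "store_in_km": 0.5,
  "store_out_vmax": 40.0,
  "store_out_km": 5.0,
  "slow_frac": 0.1,
  "slow_k": 3.0,
  "ca_basal": 0.05,
  "f0": 1.0,
  "sigma": 0.0
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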