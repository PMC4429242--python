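{
 "cco_tot": {
  "value": 0.0022,
  "unit": "mM",
  "lower": 0.00055,
  "upper": 0.0088
 },
 "lac_n": {
  "value": 3.0,
  "unit": "mM",
  "lower": 1.5,
  "upper": 6.0
 },
 "hbtot_n": {
  "value": 5.4,
  "unit": "mM",
  "lower": 3.78,
  "upper": 8.100000000000001
 },
 "pa_n": {
  "value": 50.0,
  "unit": "mmHg",
  "lower": 42.5,
  "upper": 57.49999999999999
 },
 "ph_m_n": {
  "value": 7.0495,
  "unit": "pH",
  "lower": 6.9,
  "upper": 7.2
 },
 "k_aut": {
  "value": 1.0,
  "unit": "1",
  "lower": 0.5,
  "upper": 1.0
 },
 "r_m": {
  "value": 0.0126,
  "unit": "cm",
  "lower": 0.011340000000000001,
  "upper": 0.01386
 },
 "oxfrac_n": {
  "value": 0.67,
  "unit": "1",
  "lower": 0.6030000000000001,
  "upper": 0.7370000000000001
 },
 "f_carotid": {
  "value": 0.8,
  "unit": "1",
  "lower": 0.6,
  "upper": 0.95
 },
 "glu_rate_n": {
  "value": 0.0044,
  "unit": "mM/s",
  "lower": 0.00308,
  "upper": 0.00616
 }
}
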