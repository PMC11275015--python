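{
  "name": "AgBH",
  "d001_nm": 5.838,
  "n_orders": 30,
  "note": "Silver behenate layered calibration standard; ring n sits at q_n = 2*pi*n/d001. d001 from the standard calibrant literature; override by constructing a CalibrantSpec directly."
}
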