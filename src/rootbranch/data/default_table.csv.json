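{
 "format_version": 1,
 "grid_spec": {
  "isd": [
   0.3,
   0.822222,
   1.344444,
   1.866667,
   2.388889,
   2.911111,
   3.433333,
   3.955556,
   4.477778,
   5.0
  ],
  "cv_d": [
   0.1,
   0.177778,
   0.255556,
   0.333333,
   0.411111,
   0.488889,
   0.566667,
   0.644444,
   0.722222,
   0.8
  ],
  "p_em": [
   0.3,
   0.377778,
   0.455556,
   0.533333,
   0.611111,
   0.688889,
   0.766667,
   0.844444,
   0.922222,
   1.0
  ]
 },
 "n_laterals": 20000,
 "seed": 20190808
}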