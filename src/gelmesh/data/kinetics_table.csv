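system_id,zero_r2,zero_k0,first_r2,first_k1,higuchi_r2,higuchi_kH,kp_r2,kp_kKP,kp_n
PN-0-L-298,-0.211,0.059,0.912,0.172,0.894,0.236,0.961,0.295,0.360
PN-0-H-298,-0.411,0.060,0.902,0.190,0.847,0.244,0.974,0.318,0.337
PN-0-L-310,-0.394,0.060,0.914,0.192,0.852,0.244,0.990,0.310,0.348
PN-0-H-310,-0.410,0.061,0.922,0.202,0.829,0.249,0.931,0.314,0.312
CA-5-L-298,-0.392,0.060,0.930,0.188,0.868,0.242,0.995,0.300,0.382
CA-5-H-298,-0.290,0.060,0.905,0.183,0.865,0.241,0.967,0.302,0.370
CA-5-L-310,-1.130,0.063,0.928,0.248,0.698,0.260,0.999,0.361,0.289
CA-5-H-310,-0.892,0.061,0.921,0.215,0.794,0.249,0.989,0.324,0.408
CA-15-L-298,-0.609,0.060,0.907,0.200,0.831,0.246,1.000,0.330,0.329
CA-15-H-298,-0.328,0.059,0.889,0.179,0.871,0.239,0.996,0.312,0.347
CA-15-L-310,-0.126,0.059,0.886,0.175,0.864,0.239,0.993,0.293,0.366
CA-15-H-310,-0.736,0.062,0.910,0.224,0.767,0.256,0.995,0.350,0.270
CA-20-L-298,-0.751,0.061,0.901,0.209,0.799,0.249,0.969,0.346,0.295
CA-20-H-298,-0.926,0.062,0.880,0.223,0.750,0.254,0.996,0.370,0.256
CA-20-L-310,-0.516,0.062,0.951,0.211,0.827,0.250,0.998,0.304,0.379
CA-20-H-310,-0.954,0.061,0.910,0.224,0.772,0.252,0.999,0.332,0.393
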