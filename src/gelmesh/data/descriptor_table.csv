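system_id,D_1e7_cm2_s,f_det_pct,hb_polymer_polymer,hb_polymer_drug,pld_A,pld_sd_A,mpd_A,mpd_sd_A
PN-0-L-298,4.67,4,9.60,6.22,6.17,0.71,12.44,0.74
PN-0-H-298,5.97,12,16.28,0.04,5.95,0.60,11.55,0.17
PN-0-L-310,1.52,2,9.80,4.88,6.75,0.61,10.34,0.28
PN-0-H-310,6.09,8,14.61,0,5.10,0.70,12.44,0.87
CA-5-L-298,0.92,0,9.29,7.07,5.66,0.16,10.39,0.48
CA-5-H-298,3.28,8,9.70,0.04,8.70,0.88,10.87,0.51
CA-5-L-310,1.45,0,10.87,7.12,5.30,0.42,8.85,0.54
CA-5-H-310,3.83,10,12.26,0,6.55,0.30,13.77,0.95
CA-15-L-298,1.53,0,12.02,6.71,6.33,0.54,10.67,0.48
CA-15-H-298,4.87,12,8.32,0.2,5.88,0.78,12.46,0.55
CA-15-L-310,1.96,0,9.27,9.71,6.99,0.72,12.20,0.76
CA-15-H-310,8.61,22,10.18,0.01,8.37,0.64,12.23,0.23
CA-20-L-298,1.60,0,10.87,6.77,7.31,0.67,10.51,1.09
CA-20-H-298,1.60,2,10.38,0.08,5.82,0.51,10.67,0.89
CA-20-L-310,2.42,2,11.35,6.01,5.97,0.53,11.33,0.69
CA-20-H-310,1.32,2,5.82,0.01,5.39,1.02,12.85,0.13
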