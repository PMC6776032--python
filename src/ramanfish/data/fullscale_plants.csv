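plant,design,qfish_acc_pct,qfish_acc_sd,qfish_tet_pct,qfish_tet_sd,polyp_acc_e13g,polyp_acc_sd_e13g,polyp_tet_e13g,polyp_tet_sd_e13g,orthop_n_mgl,orthop_n_sd_mgl,totalp_mgpgss,totalp_sd_mgpgss,frac_acc_mgpgss,frac_acc_sd_mgpgss,contrib_acc_pct,frac_tet_mgpgss,frac_tet_sd_mgpgss,contrib_tet_pct
Hjoerring,Rec (An),1.20,0.5,6.50,0.6,4.63,0.3,0.86,0.23,0.43,0.041,21.72,2.7,2.08,0.1,9.5,6.72,0.51,30.9
Randers,Rec (Hyd),2.34,0.7,6.64,0.2,4.08,0.41,1.35,0.15,0.45,0.26,22.74,0.48,3.4,0.39,14.9,10.57,0.34,46.5
Viby,Rec (Hyd),2.72,1.3,2.55,0.7,3.14,0.39,0.98,0.29,0.57,0.22,24.81,1.2,3.13,0.22,12.6,2.91,0.21,11.7
Bjerringbro,Alt (An),4.96,1.4,3.53,0.2,4.02,0.39,1.25,0.34,0.55,0.01,17.75,0.92,7.35,0.44,41.4,5.19,0.29,29.2
Aalborg East,Alt (Hyd),1.60,0.6,2.20,0.9,4.63,0.49,1.33,0.17,0.53,0.07,22.51,3.1,2.77,0.72,12.3,3.80,0.37,16.9
Aalborg West,Alt (Hyd),3.60,1.6,3.10,1.6,3.68,0.39,1.39,0.20,1.01,0.21,37.52,2.9,5.04,0.28,13.4,5.17,0.33,13.8
Egaa,Alt (An/Hyd),1.71,0.4,2.04,0.8,4.22,0.36,1.47,0.41,0.28,0.02,17.33,0.35,2.66,0.24,15.4,3.47,0.39,20
Aaby,Alt (An/Hyd),2.53,1.4,3.84,1.1,3.83,0.18,1.29,0.62,0.33,0.12,14.84,0.74,3.55,0.64,23.9,5.70,0.47,38.4
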