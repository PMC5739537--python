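pdb_id,n_residues_whole,n_residues_surface,n_epitope_residues,n_designs_crystal,n_designs_model,fnat_crystal,fnat_model,tm_score_ab,tm_score_ag,n_decoys_crystal,n_decoys_model,success_iedb_crystal,success_interface_crystal,success_iedb_model,success_interface_model
1FE8,196,124,27,4,3,0.10,0.04,0.96,0.84,30,24,T,T,F,F
1FNS,196,120,12,5,2,0.39,0.09,0.96,0.86,26,20,T,T,T,T
1H0D,123,96,14,3,2,0.00,0.05,0.98,0.79,30,30,F,F,T,T
1LK3,160,102,26,3,3,0.73,0.44,0.97,0.74,23,29,T,T,T,T
1OAZ,123,101,14,2,2,0.10,0.10,0.97,0.77,30,29,F,F,F,F
1OB1,99,74,13,3,4,0.62,0.61,0.97,0.85,30,29,T,T,T,T
1RJL,95,82,13,3,2,0.29,0.30,0.96,0.89,30,27,T,T,T,T
1V7M,163,113,20,6,3,0.45,0.19,0.96,0.78,27,24,T,T,T,T
1YJD,140,86,14,2,3,0.42,0.13,0.98,0.77,25,30,T,T,T,T
2ARJ,123,90,17,3,3,0.63,0.26,0.97,0.75,24,30,T,T,T,T
2VXQ,96,71,21,3,3,0.32,0.21,0.89,0.89,30,30,T,T,T,T
2VXT,157,116,19,3,3,0.83,0.13,0.95,0.93,13,19,T,T,T,T
2XQB,114,87,18,2,3,0.16,0.25,0.92,0.89,17,21,T,T,T,T
3D9A,129,93,19,3,2,0.09,0.63,0.93,0.93,22,29,T,T,T,T
3HI1,290,246,20,4,3,0.28,0.02,0.97,0.83,30,29,F,F,F,F
3L5X,113,83,8,6,3,0.18,0.24,0.98,0.83,30,30,T,T,T,T
3MXW,169,108,22,2,2,0.52,0.47,0.96,0.92,20,23,T,T,T,T
3QWO,57,48,10,3,4,0.32,0.53,0.96,0.86,30,30,T,T,T,T
3RKD,146,105,18,5,3,0.55,0.48,0.97,0.49,30,30,T,T,T,T
4DN4,76,50,12,2,2,0.49,0.28,0.92,0.88,20,27,T,T,T,T
4DW2,222,175,20,4,3,0.10,0.35,0.92,0.85,30,30,T,T,T,T
4ETQ,226,186,22,4,3,0.45,0.57,0.96,0.94,30,30,T,T,T,T
4G3Y,157,114,12,3,4,0.35,0.12,0.94,0.86,30,30,T,T,T,T
4G6J,158,109,13,3,3,0.57,0.15,0.97,0.85,30,30,T,T,T,T
4I3S,190,163,23,4,4,0.05,0.09,0.81,0.82,30,30,T,T,T,T
4JZJ,252,210,18,4,6,0.31,0.25,0.95,0.33,30,30,T,T,T,T
4KI5,183,108,7,1,1,0.39,0.29,0.95,0.93,24,20,T,T,T,T
4L5F,111,79,9,2,3,0.52,0.10,0.97,0.80,30,30,T,T,T,T
4LVH,223,184,13,5,6,0.12,0.05,0.93,0.90,30,29,T,T,F,T
4M62,155,105,6,2,2,0.12,0.11,0.92,0.81,24,24,T,T,F,T
4NP4,272,230,25,3,5,0.09,0.07,0.96,0.67,30,30,T,T,T,T
4RGO,226,187,17,3,6,0.16,0.21,0.97,0.96,30,30,F,T,T,T
5D96,235,198,22,4,4,0.23,0.15,0.95,0.96,30,30,T,T,T,T
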