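config,phenotype,dose,K_in,K_in_se,K_out,K_out_se
BNF-Plain,M0,0.125,0.00146,0.00150,0.13862,0.20191
BNF-Plain,M0,0.250,0.00070,0.00012,0.11676,0.03122
BNF-Plain,M0,0.500,0.00061,0.00022,0.09149,0.05568
BNF-Plain,M0,average,0.00092,0.00051,0.11562,0.07059
BNF-Plain,M1,0.125,0.00099,0.00023,0.00000,0.02115
BNF-Plain,M1,0.250,0.00101,0.00029,0.00000,0.02621
BNF-Plain,M1,0.500,0.00103,0.00027,0.00000,0.02408
BNF-Plain,M1,average,0.00101,0.00015,0.00000,0.01380
BNF-Plain,M2,0.125,0.00079,0.00021,0.08162,0.03797
BNF-Plain,M2,0.250,0.00057,0.00018,0.06572,0.04289
BNF-Plain,M2,0.500,0.00048,0.00014,0.06319,0.03955
BNF-Plain,M2,average,0.00061,0.00010,0.07018,0.02320
BNF-Her,M0,0.125,0.00103,0.00007,0.08675,0.01000
BNF-Her,M0,0.250,0.00150,0.00075,0.09434,0.07842
BNF-Her,M0,0.500,0.00088,0.00014,0.00000,0.01436
BNF-Her,M0,average,0.00114,0.00025,0.06036,0.02678
BNF-Her,M1,0.125,0.00267,0.00091,0.00000,0.03106
BNF-Her,M1,0.250,0.00232,0.00058,0.00000,0.02281
BNF-Her,M1,0.500,0.00215,0.00080,0.00000,0.03412
BNF-Her,M1,average,0.00238,0.00045,0.00000,0.01716
BNF-Her,M2,0.125,0.00103,0.00040,0.06352,0.05048
BNF-Her,M2,0.250,0.00114,0.00052,0.06970,0.06238
BNF-Her,M2,0.500,0.00088,0.00026,0.00000,0.02754
BNF-Her,M2,average,0.00102,0.00024,0.04441,0.02828
BNF-IgG,M0,0.125,0.00100,0.00050,0.13548,0.09770
BNF-IgG,M0,0.250,0.00075,0.00018,0.11884,0.04218
BNF-IgG,M0,0.500,0.00083,0.00029,0.13587,0.06790
BNF-IgG,M0,average,0.00086,0.00020,0.13006,0.04208
BNF-IgG,M1,0.125,0.00129,0.00038,0.00682,0.02855
BNF-IgG,M1,0.250,0.00131,0.00033,0.00000,0.02288
BNF-IgG,M1,0.500,0.00137,0.00036,0.01692,0.02647
BNF-IgG,M1,average,0.00132,0.00021,0.00791,0.01505
BNF-IgG,M2,0.125,0.00102,0.00064,0.14503,0.12777
BNF-IgG,M2,0.250,0.00074,0.00024,0.11689,0.05677
BNF-IgG,M2,0.500,0.00086,0.00045,0.14133,0.10473
BNF-IgG,M2,average,0.00087,0.00027,0.13442,0.05823
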