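diameter_nm,lambda_b,lambda_b_se,lambda_p,lambda_p_se,K_pb,K_pb_se,K_el,K_el_se,K_bp,K_bp_se
20,20.169,1.999,0.043,0.003,9.085,1.039,0.095,0.016,11.032,2.253
30,9.304,0.641,0.038,0.006,2.325,0.238,0.151,0.031,6.866,0.685
100,20.273,0.348,0.052,0.005,2.241,0.094,0.471,0.050,17.613,0.364
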