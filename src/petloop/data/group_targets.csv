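roi,side,metric,healthy_mean,healthy_sd,gad_mean,gad_sd,n_per_group,t_printed,significant_printed
prefrontal,left,peak,2.41,0.21,2.04,0.20,20,5.71,1
prefrontal,right,peak,2.52,0.24,2.06,0.18,20,6.86,1
striatum,left,peak,1.95,0.17,1.41,0.19,20,9.47,1
striatum,right,peak,1.97,0.22,1.97,0.18,20,0.00,0
hippocampus,left,peak,1.65,0.20,1.16,0.15,20,8.77,1
hippocampus,right,peak,1.63,0.19,1.63,0.16,20,0.00,0
thalamus,left,peak,1.71,0.17,2.13,0.24,20,6.39,1
thalamus,right,peak,1.69,0.15,2.08,0.20,20,6.98,1
prefrontal,left,pre_rate,0.34,0.02,0.15,0.01,20,38.00,1
prefrontal,right,pre_rate,0.24,0.02,0.15,0.02,20,14.23,1
striatum,left,pre_rate,0.14,0.01,0.09,0.01,20,15.81,1
striatum,right,pre_rate,0.09,0.01,0.09,0.01,20,0.00,0
hippocampus,left,pre_rate,0.12,0.02,0.06,0.01,20,12.00,1
hippocampus,right,pre_rate,0.11,0.02,0.11,0.01,20,0.00,0
thalamus,left,pre_rate,0.21,0.02,0.45,0.03,20,29.77,1
thalamus,right,pre_rate,0.08,0.01,0.14,0.01,20,18.97,1
prefrontal,left,post_rate,0.07,0.01,0.10,0.01,20,9.49,1
prefrontal,right,post_rate,0.05,0.02,0.12,0.02,20,11.07,1
striatum,left,post_rate,0.08,0.01,0.03,0.01,20,15.81,1
striatum,right,post_rate,0.12,0.02,0.11,0.02,20,1.58,0
hippocampus,left,post_rate,0.09,0.01,0.05,0.01,20,12.65,1
hippocampus,right,post_rate,0.11,0.02,0.10,0.01,20,2.10,0
thalamus,left,post_rate,0.05,0.01,0.08,0.01,20,9.49,1
thalamus,right,post_rate,0.10,0.01,0.09,0.02,20,2.10,0
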