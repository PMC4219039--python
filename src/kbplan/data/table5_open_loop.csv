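patient,endpoint,clinical,open_loop_1,open_loop_2
1,normal_liver_v30,30.5,27.4,30.6
2,right_kidney_v15,46.9,39.7,23.6
3,right_kidney_v15,38.5,34.8,34.4
4,normal_liver_v30,29.3,31.0,29.9
5,right_kidney_v15,31.8,36.9,20.5
6,right_kidney_v15,38.6,36.6,21.5
6,ptv_d98,94.8,89.3,89.8
7,normal_liver_v30,32.1,32.5,33.1
8,normal_liver_v30,36.3,30.0,39.5
9,right_kidney_v15,49.9,26.9,17.0
10,right_kidney_v15,38.9,26.5,25.0
11,right_kidney_v15,46.3,25.6,22.7
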