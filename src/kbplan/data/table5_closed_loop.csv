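patient,endpoint,clinical,closed_loop
1,normal_liver_v30,31.7,31.9
2,normal_liver_v30,30.6,29.4
3,normal_liver_v30,34.8,29.8
4,spinal_cord_d1cc,45.3,40.3
4,left_kidney_v15,39.2,14.6
4,right_kidney_v15,53.8,39.9
4,normal_liver_v30,51.4,36.9
5,right_kidney_v15,77.4,38.3
5,normal_liver_v30,31.8,23.3
6,right_kidney_v15,41.6,19.4
7,right_kidney_v15,43.6,26.7
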