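d2o_percent,adapted,light_intensity,division_number,percent_of_control,doubling_time,fold_retardation
0,False,150,6.96,100,9.98,1
0,False,200,7.44,100,9.05,1
0,False,300,8.27,100,8.79,1
0,False,400,9.35,100,7.98,1
70,False,150,4.77,68.53,22.80,2.28
70,False,200,4.54,61.00,13.35,1.48
70,False,300,3.92,47.45,11.17,1.27
70,False,400,4.76,50.85,9.28,1.16
99,False,150,1.33,19.07,117.32,11.75
99,False,200,1.38,18.49,86.27,9.53
99,False,300,1.64,19.88,158.68,18.04
99,False,400,1.14,12.23,145.78,18.28
99,True,150,1.36,19.52,34.32,3.44
99,True,200,1.12,15.05,46.13,5.10
99,True,300,1.20,14.48,,
99,True,400,1.43,15.31,,
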