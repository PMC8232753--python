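d2o_percent,adapted,light_intensity,mass_multiplication_factor,percent_of_control,mass_doubling_time,fold_retardation
0,False,150,4.33,100,12.79,1
0,False,200,5.65,100,11.65,1
0,False,300,5.54,100,13.65,1
0,False,400,5.74,100,10.60,1
70,False,150,3.64,84.13,15.29,1.20
70,False,200,3.42,60.52,13.75,1.18
70,False,300,3.32,59.86,16.04,1.18
70,False,400,4.03,70.27,13.24,1.25
99,False,150,1.83,42.39,118.23,9.24
99,False,200,1.29,22.73,142.92,12.26
99,False,300,1.13,20.43,306.28,22.44
99,False,400,1.05,18.23,309.10,29.17
99,True,150,3.18,73.46,42.53,3.33
99,True,200,2.78,49.20,47.62,4.09
99,True,300,2.78,50.25,49.99,3.66
99,True,400,2.11,36.68,49.09,4.63
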