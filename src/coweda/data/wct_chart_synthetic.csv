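t_air_c,0,1,2,3,4,5,6,7,8,9,10,11,12,13,14,15,16,17,18,19,20,21,22,23,24,25
5.0,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited
2.5,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited
0.0,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited
-2.5,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited
-5.0,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited
-7.5,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited
-10.0,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited
-12.5,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,30 min,30 min
-15.0,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min
-17.5,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,unlimited,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min
-20.0,unlimited,unlimited,unlimited,unlimited,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min
-22.5,unlimited,unlimited,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min
-25.0,unlimited,unlimited,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min
-27.5,unlimited,unlimited,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,10 min,10 min,10 min,10 min,10 min,10 min
-30.0,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min
-32.5,30 min,30 min,30 min,30 min,30 min,30 min,30 min,30 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min
-35.0,30 min,30 min,30 min,30 min,30 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,5 min,5 min,5 min,5 min
-37.5,30 min,30 min,30 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min
-40.0,30 min,30 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,10 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min
-42.5,30 min,30 min,10 min,10 min,10 min,10 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min
-45.0,30 min,30 min,10 min,10 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min,5 min
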