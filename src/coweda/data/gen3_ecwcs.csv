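name,rt_head,rt_torso,rt_arm,rt_hand,rt_leg,rt_foot,re_head,re_torso,re_arm,re_hand,re_leg,re_foot
Gen III ECWCS lightweight cold weather undershirt,0.000,0.086,0.064,0.007,0.002,0.000,0.00,9.86,6.52,0.00,1.02,0.00
Gen III ECWCS lightweight cold weather drawers,0.000,0.022,0.000,0.000,0.052,0.000,0.00,3.31,0.00,0.00,6.81,0.00
Gen III ECWCS midweight cold weather shirt,0.004,0.107,0.105,0.013,0.000,0.000,0.32,12.96,13.33,0.00,0.00,0.00
Gen III ECWCS midweight cold weather drawers,0.000,0.026,0.000,0.000,0.092,0.000,0.00,3.41,0.00,0.00,10.08,0.00
Gen III ECWCS fleece cold weather jacket,0.008,0.163,0.204,0.000,0.001,0.000,0.47,14.20,21.70,0.00,0.03,0.00
Gen III ECWCS cold weather wind jacket,0.000,0.109,0.085,0.000,0.001,0.000,0.00,13.63,16.27,0.00,0.00,0.00
Gen III ECWCS soft shell jacket,0.005,0.147,0.101,0.000,0.001,0.000,0.09,46.13,55.94,0.00,0.00,0.00
Gen III ECWCS soft shell trouser,0.000,0.045,0.000,0.000,0.117,0.000,0.00,8.06,0.00,0.00,70.57,0.00
Gen III ECWCS cold wet weather jacket,0.003,0.136,0.107,0.000,0.001,0.000,0.00,34.25,31.81,0.00,0.00,0.00
Gen III ECWCS cold wet weather trouser,0.000,0.031,0.000,0.000,0.109,0.000,0.00,5.58,0.00,0.00,39.38,0.00
Gen III ECWCS extreme cold weather parka (stowed hood),0.000,0.572,0.456,0.000,0.002,0.000,0.00,65.91,65.41,0.00,0.00,0.00
Gen III ECWCS extreme cold weather trouser,0.000,0.052,0.000,0.000,0.387,0.000,0.00,7.41,0.00,0.00,69.06,0.00
Gen III ECWCS extreme cold weather parka (freed hood),0.141,0.572,0.456,0.000,0.002,0.000,29.87,65.91,65.41,0.00,0.00,0.00
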