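animal,infarct_volume,total_neuroscore,mean_velocity,mean_head_to_T1,swing_duration_right,swing_duration_left,stance_duration_left,min_fetlock_swing_left
1,18.49,7.5,0.90,2.31,0.40,0.41,0.60,-18.31
2,0.35,16.25,0.67,-3.42,0.42,0.54,0.62,-44.21
3,1.99,7.5,0.88,-0.15,0.36,0.37,0.60,-18.14
4,3.66,12.5,0.92,-3.63,0.38,0.35,0.55,-9.38
5,4.07,11.5,0.96,-2.93,0.39,0.36,0.59,-28.61
6,3.19,15.5,0.91,-4.69,0.38,0.38,0.64,-25.78
7,0.90,2.5,1.28,11.22,0.37,0.38,0.41,-28.02
8,0.63,5,1.17,5.14,0.38,0.36,0.44,-37.84
9,5.28,0.5,1.19,3.66,0.35,0.36,0.43,-34.27
10,0.84,10,1.29,15.39,0.35,0.35,0.36,-8.91
11,2.68,4.5,1.18,8.33,0.36,0.34,0.39,-15.22
12,1.53,5,1.24,4.53,0.35,0.34,0.41,-50.90
13,21.99,9.5,0.68,-5.33,0.36,0.40,0.72,-33.65
14,25.46,12,0.97,1.01,0.42,0.42,0.59,-16.65
15,2.66,6.25,0.88,-0.67,0.39,0.39,0.63,-30.20
16,2.01,4.25,0.98,7.49,0.38,0.37,0.50,-26.39
17,1.26,2.25,0.95,11.40,0.39,0.40,0.53,-13.97
18,19.33,7.5,0.96,6.23,0.35,0.35,0.56,-20.67
19,29.95,12,1.12,-19.41,0.40,0.36,0.60,-6.02
20,1.71,8.25,1.20,5.72,0.34,0.31,0.42,-12.60
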