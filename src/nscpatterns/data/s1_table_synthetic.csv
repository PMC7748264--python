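hemisphere,delta_t,n_nsc,s_t1,s_t2,nsc_s_t1,nsc_s_t2,redivisions,nsc_redivisions,dls,nsc_dls
h01,9.0,2385,112,110,52,51,0,0,53,24
h02,9.0,3140,86,82,55,53,0,0,48,33
h03,9.0,3233,87,92,49,52,0,0,39,25
h04,9.0,2712,88,68,52,40,0,0,40,20
h05,9.0,2759,97,107,50,55,0,0,44,26
h06,9.0,2323,57,87,26,40,0,0,28,11
h07,18.0,2118,70,63,44,40,1,0,3,2
h08,18.0,2124,69,73,40,42,3,2,1,1
h09,18.0,2077,85,81,41,39,0,0,1,1
h10,18.0,3007,123,102,59,49,3,3,8,5
h11,18.0,2532,88,78,50,44,0,0,3,3
h12,18.0,2621,116,83,53,38,2,0,1,0
h13,24.0,2250,98,55,60,34,5,3,0,0
h14,24.0,2034,107,83,49,38,5,5,0,0
h15,24.0,1979,70,75,33,35,2,1,1,1
h16,24.0,2153,73,65,47,42,2,2,0,0
h17,24.0,2848,133,104,67,52,3,2,0,0
h18,24.0,2568,76,104,37,51,0,0,0,0
h19,32.0,2338,63,74,40,47,6,2,0,0
h20,32.0,2443,84,92,42,46,11,5,0,0
h21,32.0,1870,49,74,31,47,5,4,0,0
h22,32.0,3153,82,86,52,55,2,1,0,0
h23,32.0,1972,88,59,49,33,3,1,0,0
h24,32.0,2579,90,75,55,46,5,3,0,0
h25,48.0,3590,123,145,62,73,11,4,0,0
h26,48.0,1328,47,50,28,30,5,2,0,0
h27,48.0,1880,73,55,43,32,7,7,0,0
h28,48.0,2210,73,64,48,42,9,5,0,0
h29,48.0,2615,102,87,54,46,4,1,0,0
h30,48.0,1731,59,71,31,37,5,3,0,0
h31,72.0,2445,89,76,45,38,4,1,0,0
h32,72.0,2545,66,91,31,43,5,2,0,0
h33,72.0,2641,104,67,54,35,6,2,0,0
h34,72.0,1406,43,55,23,29,0,0,0,0
h35,72.0,2871,103,90,63,55,8,5,0,0
h36,72.0,3327,135,102,73,55,5,2,0,0
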