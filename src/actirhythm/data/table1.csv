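patient_id,age,sex,etiology,months_since_injury,diagnosis,crs_r_sum,excluded
P1,43,M,NTBI,39.0,EMCS,11,False
P2,72,F,NTBI,10.0,UWS,6,False
P3,25,M,NTBI,99.0,UWS,6,False
P4,34,M,TBI,15.0,UWS,6,False
P5,60,M,NTBI,7.0,UWS,7,False
P6,49,F,NTBI,16.0,UWS,6,False
P7,50,M,NTBI,4.0,UWS,3,False
P8,59,F,NTBI,6.0,UWS,6,False
P9,60,M,NTBI,7.0,UWS,7,False
P10,68,M,NTBI,5.0,UWS,6,False
P11,70,F,TBI,7.0,UWS,3,False
P12,48,F,NTBI,37.0,UWS,5,False
P13,66,M,NTBI,2.0,UWS,7,False
P14,20,M,TBI,56.0,MCS,13,False
P15,71,M,NTBI,24.0,UWS,1,False
P16,55,F,TBI,168.0,MCS,17,False
P17,70,F,NTBI,15.0,UWS,3,False
P18,51,M,TBI,54.0,UWS,4,False
P19,61,F,NTBI,9.0,EMCS,23,False
P20,68,M,NTBI,415.0,UWS,4,False
P21,53,F,NTBI,10.5,MCS,13,False
P22,68,F,TBI,13.5,MCS,9,False
P23,71,F,TBI,2.5,EMCS,23,False
P24,53,F,NTBI,82.0,UWS,5,False
P25,37,M,TBI,197.0,MCS,9,False
P26,46,F,NTBI,3.0,UWS,4,True
P27,19,F,TBI,17.0,MCS,8,False
P28,78,M,NTBI,13.0,MCS,9,False
P29,27,M,NTBI,1.5,UWS,4,False
P30,54,M,TBI,10.0,EMCS,20,False
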