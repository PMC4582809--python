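patient,group,row_type,close,distant,living_close,living_distant,nonliving_close,nonliving_distant
P2,vATL-damaged,patient,42,82,47,83,37,80
P3,vATL-damaged,patient,80,95,77,93,83,97
P4,vATL-damaged,patient,60,72,57,77,63,67
P5,vATL-damaged,patient,75,98,73,97,77,100
P6,vATL-damaged,patient,65,95,57,93,73,97
P8,vATL-damaged,patient,70,98,70,100,70,97
P9,vATL-intact,patient,90,100,90,100,90,100
P10,vATL-intact,patient,75,97,73,97,77,97
P12,vATL-intact,patient,60,100,57,100,63,100
P14,vATL-intact,patient,80,100,83,100,77,100
,vATL-damaged,mean,65,90,63,91,67,89
,vATL-intact,mean,76,99,76,99,77,99
,control,mean,80,96,78,96,82,96
,vATL-damaged,sem,6,4,5,4,7,5
,vATL-intact,sem,6,1,7,1,5,1
,control,sem,2,1,2,1,2,1
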