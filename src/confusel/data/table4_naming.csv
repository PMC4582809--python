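patient,group,row_type,all,living,nonliving,animal,tool,fruit_veg,vehicle
P1,vATL-damaged,patient,98,99,97,100,100,97,100
P2,vATL-damaged,patient,46,45,47,42,52,42,78
P3,vATL-damaged,patient,92,92,92,85,88,97,100
P4,vATL-damaged,patient,87,84,90,85,88,73,94
P5,vATL-damaged,patient,94,92,96,91,96,94,100
P6,vATL-damaged,patient,79,73,83,79,84,64,94
P7,vATL-damaged,patient,85,80,88,79,88,82,89
P8,vATL-damaged,patient,84,83,85,76,88,88,94
P9,vATL-intact,patient,98,98,98,97,100,97,100
P10,vATL-intact,patient,95,96,95,94,96,94,89
P11,vATL-intact,patient,88,90,87,88,84,94,100
P12,vATL-intact,patient,92,89,95,79,92,94,100
P13,vATL-intact,patient,95,97,93,94,92,100,100
P14,vATL-intact,patient,94,92,95,91,100,91,94
,vATL-damaged,mean,83,81,85,80,86,80,94
,vATL-intact,mean,94,93,94,90,94,95,97
,control,mean,94,94,94,92,94,95,96
,vATL-damaged,sem,5.7,5.9,5.6,6.0,5.1,6.8,2.7
,vATL-intact,sem,1.3,1.5,1.5,2.6,2.5,1.3,1.9
,control,sem,0.7,1.3,0.9,1.2,1.7,1.7,1.2
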