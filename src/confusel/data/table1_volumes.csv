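patient,group,sex,age_at_onset,years_to_first_test,aetiology,lesion_volume_cm3
P1,vATL-damaged,F,54.8,7.5,Excision of meningioma,12.9
P2,vATL-damaged,M,59.6,11.3,Haematoma,18.4
P3,vATL-damaged,M,41.0,7.0,Abscess,5.8
P4,vATL-damaged,M,52.7,9.7,Excision of meningioma,27.0
P5,vATL-damaged,M,36.0,11.8,AV malformation and haematoma,15.5
P6,vATL-damaged,M,43.0,13.0,Resection for epilepsy,17.5
P7,vATL-damaged,F,46.7,21.4,Meningioma,12.6
P8,vATL-damaged,F,27.6,3.1,Excision of tumour,10.0
P9,vATL-intact,M,40.0,4.8,Haemorrhagic stroke,4.6
P10,vATL-intact,F,19.7,15.2,Ischaemic stroke,6.8
P11,vATL-intact,M,32.8,4.8,Glioma,12.8
P12,vATL-intact,M,42.5,17.5,Ischaemic stroke,42.0
P13,vATL-intact,F,47.6,4.5,Ischaemic stroke,9.7
P14,vATL-intact,M,22.6,5.5,Cavernoma,8.5
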