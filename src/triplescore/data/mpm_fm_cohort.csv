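patient_id,p16_pct,cd8_pct,ki67_pct,cdkn2a,split,reported_total
SV001,50,0,40,Disomy,test,8
MS002,50,20,20,Heterozygous deletion,test,5
IM003,50,0,25,Heterozygous deletion,test,8
HV004,0,0,40,Homozygous deletion,test,10
CV005,50,20,60,Heterozygous deletion,test,5
RI006,0,5,60,Homozygous deletion,test,9
PC007,50,0,10,Disomy,test,6
BN008,50,20,10,Monosomy,test,4
MR009,50,70,60,Monosomy,test,5
MI010,0,5,60,Homozygous deletion,validation,9
PS011,50,10,10,Disomy,test,5
AM012,50,40,70,Disomy,validation,6
GN013,0,0,40,Homozygous deletion,validation,10
CM014,0,0,50,Homozygous deletion,validation,10
CN015,50,5,50,Disomy,validation,7
GU016,50,10,10,Disomy,validation,5
SM017,50,0,60,Monosomy,test,8
MS018,0,0,20,Homozygous deletion,validation,9
VS019,0,0,80,Monosomy,validation,10
LV020,0,90,20,Monosomy,validation,6
PD021,50,5,30,Disomy,validation,7
PG022,50,5,10,Monosomy,validation,5
TV023,0,0,50,Homozygous deletion,validation,10
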