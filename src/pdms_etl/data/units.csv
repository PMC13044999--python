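unit,dimension,factor_to_base
ug,mass,0.001
µg,mass,0.001
mcg,mass,0.001
mg,mass,1
g,mass,1000
mL,volume,1
ml,volume,1
L,volume,1000
l,volume,1000
U,activity,1
IU,activity,1
s,time,0.0002777777777777778
min,time,0.016666666666666666
h,time,1
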