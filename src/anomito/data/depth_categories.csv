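label,min_m,max_m,temperature_c,oxygen_mg_l,pressure_atm
Terrestrial,,,Variable,Variable,1
Intertidal,0,30,10-25,6-8,1-3
Shallow,30,200,8-20,4-7,3-20
Upper bathyal,200,1000,4-8,2-5,20-100
Deep sea,1000,,0-4,1-3,100-600
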