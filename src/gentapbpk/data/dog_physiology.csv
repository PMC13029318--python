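name,volume_per_kg,flow_per_kg,f_water,f_lipid,f_protein
arterial_blood,0.027,7.20,0.81,0.002,0.17
venous_blood,0.055,7.20,0.81,0.002,0.17
muscle,0.457,1.80,0.76,0.022,0.19
adipose,0.150,0.50,0.15,0.80,0.03
kidney,0.0055,1.25,0.78,0.012,0.17
liver,0.033,2.20,0.71,0.035,0.18
rest,0.2725,1.45,0.72,0.10,0.15
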