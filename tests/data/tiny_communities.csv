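individual_id,species,site,plot,body_mass_g,back_leg_length_mm
A-1,A,site1,p1,1.0,2.0
A-2,A,site1,p1,3.0,2.0
A-3,A,site1,p2,2.0,2.0
A-4,A,site1,,2.0,2.0
B-1,B,site1,p1,4.0,4.0
B-2,B,site1,p2,5.0,4.0
B-3,B,site1,p2,7.0,4.0
C-1,C,site1,p2,10.0,8.0
C-2,C,site1,,9.0,8.0
C-3,C,site1,,11.0,8.0
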