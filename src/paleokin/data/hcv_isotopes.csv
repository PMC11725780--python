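individual,age_class,sex,tissue,d13c_col,d15n_col,d13c_en,d18o_en,pct_c4_published,pct_marine_published,sr87_86,pb208_204,pb207_204,pb206_204
B1,A,M,M3,-11.1,10.7,-6.4,-4.2,70.8,50.8,0.70882,38.724,15.655,18.847
B1s,SA,M,M1,-11.3,8.9,-6.7,-4.4,68.8,37.4,0.70697,38.713,15.632,18.851
B2,A,M,rib,-9.3,11.9,,,,70.7,,,,
B3,A,F,M1root,-12.0,10.4,,,,44.7,0.70882,38.832,15.662,18.961
B3s,SA,F,C,-13.4,8.6,-11.4,-6.1,35.0,30.3,0.70919,39.411,15.762,19.911
B4,A,M,M2,-9.9,11.5,-5.9,-4.2,74.2,64.5,0.70878,38.869,15.674,18.992
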