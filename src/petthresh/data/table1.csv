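# Validation lesions with histological major axis <= 20 mm (n=10).
# Raw measurement columns plus published delta-Vs columns (percent, 1 decimal).
# bmin/tmean are PET gray levels; areas mm^2; axes mm; cov dimensionless.
lesion_id,maaxis_hist_mm,bmin,tmean,pct_tmean,maaxis_pet_mm,maaxis_ct_mm,dvs_maaxis_pet_hist,dvs_maaxis_ct_hist,dvs_maaxis_pet_ct,area_pet_mm2,area_ct_mm2,dvs_area_pet_ct,cov
39,12,560,6407.7,74.3,14.4,11.8,20.0,-1.7,22.0,96,87.9,9.2,0.16
40,12,378,4081.7,77.1,17.9,12.7,49.2,5.8,40.9,144,90.6,58.9,0.16
41,12,374,2680.3,87.8,17.9,15.4,49.2,28.3,16.2,144,122.2,17.8,0.10
42,15,392,2939.0,86.0,14.4,17.9,-4.0,19.3,-19.6,112,94.7,18.3,0.05
43,16,151,2686.7,71.9,25.6,17.7,60.0,10.6,44.6,304,152.4,99.5,0.23
44,18,360,4098.0,76.2,17.0,16.3,-5.6,-9.4,4.3,128,144.2,-11.2,0.15
45,18,350,7216.0,65.0,20.0,18.5,11.1,2.8,8.1,208,182.6,13.9,0.25
46,19,179,5218.0,61.1,20.0,19.3,5.3,1.6,3.6,244,162.0,50.6,0.31
47,20,195,1949.3,86.2,25.6,16.7,28.0,-16.5,53.3,244,159.3,53.2,0.10
48,20,467,4571.0,78.2,26.8,23.7,34.0,18.5,13.1,400,344.7,16.0,0.15
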