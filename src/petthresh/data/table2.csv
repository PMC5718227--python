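# Validation lesions with histological major axis in 20-45 mm (n=17).
# Raw measurement columns plus published delta-Vs columns (percent, 1 decimal).
# bmin/tmean are PET gray levels; areas mm^2; axes mm; cov dimensionless.
# Lesion 52's COV was published with a decimal comma ("0,36"); stored as 0.36.
lesion_id,maaxis_hist_mm,bmin,tmean,pct_tmean,maaxis_pet_mm,maaxis_ct_mm,dvs_maaxis_pet_hist,dvs_maaxis_ct_hist,dvs_maaxis_pet_ct,area_pet_mm2,area_ct_mm2,dvs_area_pet_ct,cov
49,22,279,3566.6,75.0,20.0,18.1,-9.1,-17.7,10.5,208,160.7,29.4,0.22
50,24,278,4161.0,71.7,20.0,23.4,-16.7,-2.5,-14.5,144,255.4,-43.6,0.16
51,25,167,5040.3,60.7,28.8,17.6,15.2,-29.6,63.6,384,184.0,108.7,0.30
52,25,193,9476.0,53.3,26.8,23.7,7.2,-5.2,13.1,384,296.6,29.5,0.36
53,25,263,10442.9,55.7,25.6,24.2,2.4,-3.2,5.8,352,328.2,7.3,0.32
54,25,335,7954.2,62.8,25.6,23.7,2.4,-5.2,8.0,352,332.3,5.9,0.23
55,25,295,7441.4,62.1,28.8,25.3,15.2,1.2,13.8,384,392.8,-2.2,0.26
56,28,191,11198.8,51.1,28.8,23.4,2.9,-16.4,23.1,400,309.0,29.4,0.37
57,28,776,16033.8,63.8,26.8,33.6,-4.3,20.0,-20.2,416,589.1,-29.4,0.23
58,28,632,7253.0,73.9,28.8,36.5,2.9,30.4,-21.1,416,604.2,-31.1,0.20
59,32,541,13026.3,61.9,26.8,25.7,-16.3,-19.7,4.3,416,414.7,0.3,0.28
60,32,316,19113.9,50.3,32.2,33.0,0.6,3.1,-2.4,592,605.6,-2.2,0.34
61,35,202,15326.0,48.0,32.2,29.5,-8.0,-15.7,9.2,544,450.0,20.9,0.35
62,35,464,16213.8,56.8,35.7,33.8,2.0,-3.4,5.6,624,672.9,-7.3,0.24
63,40,394,11967.8,58.9,41.8,42.8,4.5,7.0,-2.3,1056,1064.3,-0.8,0.24
64,42,464,5558.0,74.0,37.7,40.4,-10.2,-3.8,-6.7,736,979.2,-24.8,0.15
65,45,406,13169.8,58.0,43.3,39.7,-3.8,-11.8,9.1,848,850.1,-0.2,0.31
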