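oil_id,log_ip0,k0,r_squared,shelf_life_20_days,shelf_life_25_days,group_x2
Almond oil,4.2126,0.0325,0.9979,152,105,0
Black sesame oil,4.9952,0.0405,1.0000,638,400,0
Camellia oil,4.5294,0.0372,0.9985,254,166,0
Golden linseed oil,4.5457,0.0430,0.9998,202,123,1
Peanut oil,5.3799,0.0385,1.0000,1697,1089,1
Pecan oil,4.9179,0.0391,1.0000,570,363,1
Pine nut oil,4.7509,0.0412,0.9999,352,219,1
Pumpkin seed oil,4.9211,0.0395,0.9999,564,358,
Sunflower seed oil,4.4458,0.0379,0.9992,203,131,0
Walnut oil,4.5043,0.0409,0.9996,202,126,1
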