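oil_id,sfa,ufa,pufa
Almond oil,9.55,90.44,26.64
Black sesame oil,17.43,82.58,44.33
Camellia oil,12.39,87.60,8.79
Golden linseed oil,8.85,91.16,69.66
Peanut oil,14.43,84.06,4.91
Pecan oil,10.70,89.30,31.11
Pine nut oil,9.27,90.73,61.22
Pumpkin seed oil,20.32,79.67,47.58
Sunflower seed oil,11.00,88.99,52.17
Walnut oil,8.91,91.10,76.34
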