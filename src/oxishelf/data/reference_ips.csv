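oil_id,temperature_C,ip_hours,censored
Almond oil,70,85.00,0
Almond oil,90,20.62,0
Almond oil,100,8.83,0
Black sesame oil,70,144.00,0
Black sesame oil,90,21.92,0
Black sesame oil,100,8.78,0
Camellia oil,70,85.22,0
Camellia oil,90,14.20,0
Camellia oil,100,6.63,0
Golden linseed oil,70,34.48,0
Golden linseed oil,90,4.60,0
Golden linseed oil,100,1.78,0
Peanut oil,70,,1
Peanut oil,90,81.52,0
Peanut oil,100,33.62,0
Pecan oil,70,151.00,0
Pecan oil,90,25.08,0
Pecan oil,100,10.11,0
Pine nut oil,70,74.00,0
Pine nut oil,90,10.88,0
Pine nut oil,100,4.32,0
Pumpkin seed oil,70,145.00,0
Pumpkin seed oil,90,23.05,0
Pumpkin seed oil,100,9.55,0
Sunflower seed oil,70,62.60,0
Sunflower seed oil,90,10.32,0
Sunflower seed oil,100,4.62,0
Walnut oil,70,44.47,0
Walnut oil,90,6.50,0
Walnut oil,100,2.67,0
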