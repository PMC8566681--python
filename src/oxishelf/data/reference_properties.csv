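oil_id,iodine_value,smoke_point_C,acid_value
Almond oil,101.1,174.8,0.53
Black sesame oil,109.7,172.8,3.89
Camellia oil,83.0,176.5,1.37
Golden linseed oil,187.2,134.3,1.70
Peanut oil,76.6,141.8,1.06
Pecan oil,103.9,193.7,0.23
Pine nut oil,145.5,165.8,1.51
Pumpkin seed oil,110.3,184.3,2.27
Sunflower seed oil,122.2,109.0,1.85
Walnut oil,159.4,148.3,2.26
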