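oil_id,C14:0,C16:0,C16:1,C17:0,C18:0,C18:1,C18:2,C18:3,C20:0,C20:1,C22:0
Almond oil,0.04,8.08,0.49,0.04,1.35,63.26,26.55,0.09,0.04,0.05,ND
Black sesame oil,0.02,10.93,0.12,0.03,5.82,38.01,44.33,ND,0.55,0.12,0.08
Camellia oil,0.04,10.49,0.12,0.04,1.82,78.30,8.79,ND,ND,0.39,ND
Golden linseed oil,0.36,4.68,ND,ND,3.81,21.50,15.27,54.39,ND,ND,ND
Peanut oil,0.02,7.41,0.03,0.09,3.45,79.12,4.91,ND,1.07,ND,2.39
Pecan oil,0.06,8.15,0.07,0.05,2.37,57.95,31.11,ND,0.07,0.17,ND
Pine nut oil,ND,6.22,0.08,0.04,2.59,28.04,45.13,16.09,0.35,1.39,0.07
Pumpkin seed oil,0.11,13.63,0.11,0.09,6.07,31.98,47.31,0.27,0.36,ND,0.06
Sunflower seed oil,0.06,6.75,0.09,0.03,3.38,36.61,51.97,0.2,0.18,0.12,0.60
Walnut oil,0.35,6.04,ND,ND,2.52,14.76,60.00,16.34,ND,ND,ND
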