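product,price_usd_per_mt,current_tech_low,current_tech_base_case,current_tech_high,future_tech_high
crude_palm_oil,875,3315,2364,1645,1469
high_oleic_oil,1006,3352,2402,1675,1495
low_ci_biofuel_oil,1295,3312,2363,1643,1467
lauric_acid_75,1120,3588,2533,1753,1566
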