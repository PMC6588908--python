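year,gdp_millions,workforce
2015,1483861,12664801
2020,1678852,13724099
2025,1899467,14626088
2030,2149073,15473326
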