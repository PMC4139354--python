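year,value_millions
1750,757
1800,925
1850,1227
1875,1325
1900,1643
1920,1837
1930,2029
1940,2257
1950,2516
1955,2752
1960,3020
1965,3336
1970,3698
1975,4079
1980,4448
1985,4851
1990,5292
1999,6000
2012,7000
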