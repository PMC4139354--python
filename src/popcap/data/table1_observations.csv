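year,source,value_millions
1,mcevedy_jones,170
1,kremer,170
1,biraben,252
1,blaxter,255
1,clark,256
1,haub,300
1,un1999,300
200,mcevedy_jones,190
200,kremer,190
200,biraben,257
200,blaxter,256
400,mcevedy_jones,190
400,kremer,190
400,biraben,206
400,blaxter,206
400,clark,254
500,mcevedy_jones,190
500,biraben,207
600,mcevedy_jones,200
600,kremer,200
600,biraben,208
600,blaxter,206
600,clark,237
700,mcevedy_jones,210
700,biraben,206
700,blaxter,207
800,mcevedy_jones,220
800,kremer,220
800,biraben,224
800,blaxter,224
800,clark,261
900,mcevedy_jones,240
900,biraben,222
900,blaxter,226
1000,mcevedy_jones,265
1000,kremer,265
1000,biraben,253
1000,blaxter,254
1000,clark,280
1000,un1999,310
1100,mcevedy_jones,320
1100,kremer,320
1100,biraben,299
1100,blaxter,301
1200,mcevedy_jones,360
1200,kremer,360
1200,biraben,400
1200,blaxter,400
1200,clark,384
1200,haub,450
1250,biraben,417
1250,un1999,400
1300,mcevedy_jones,360
1300,kremer,360
1300,biraben,431
1300,blaxter,432
1340,biraben,442
1340,clark,378
1400,mcevedy_jones,350
1400,kremer,350
1400,biraben,375
1400,blaxter,374
1500,mcevedy_jones,425
1500,kremer,425
1500,biraben,461
1500,blaxter,460
1500,clark,427
1500,un1999,500
1600,mcevedy_jones,545
1600,kremer,545
1600,biraben,578
1600,blaxter,579
1600,clark,498
1650,mcevedy_jones,545
1650,kremer,545
1650,clark,516
1650,haub,500
1700,mcevedy_jones,610
1700,kremer,610
1700,biraben,680
1700,blaxter,679
1700,clark,641
1750,mcevedy_jones,720
1750,kremer,720
1750,biraben,771
1750,blaxter,770
1750,clark,731
1750,haub,795
1750,un1999,790
1800,mcevedy_jones,900
1800,kremer,900
1800,biraben,954
1800,blaxter,954
1800,clark,890
1800,un1999,980
1850,mcevedy_jones,1200
1850,kremer,1200
1850,biraben,1241
1850,blaxter,1241
1850,clark,1190
1850,haub,1265
1850,un1999,1260
1875,mcevedy_jones,1325
1875,kremer,1325
1900,mcevedy_jones,1625
1900,kremer,1625
1900,biraben,1634
1900,blaxter,1633
1900,clark,1668
1900,haub,1656
1900,un1999,1650
1920,kremer,1813
1920,un1999,1860
1930,kremer,1987
1930,un1999,2070
1940,kremer,2213
1940,un1999,2300
1950,mcevedy_jones,2500
1950,kremer,2516
1950,biraben,2530
1950,blaxter,2513
1950,haub,2516
1950,un1999,2520
1955,un_census,2752
1960,un_census,3020
1965,un_census,3336
1970,un_census,3698
1975,un_census,4079
1980,un_census,4448
1985,un_census,4851
1990,un_census,5292
1999,un_census,6000
2012,un_census,7000
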