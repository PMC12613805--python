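design_id,pH,HA_added_mg_L,FA_added_mg_L,HA_ads_mg_m2,FA_ads_mg_m2,HA_sol_mg_L,FA_sol_mg_L,V_m3_m2,scenario,mode,converged,M_w_HA_ads_kDa
ExpI,4,0,0,0,0,0,0,3e-09,variable,predictive,True,17
ExpI,4,20,0,0.215174666836,0,0,0,3e-09,variable,predictive,True,17
ExpI,4,51.428571,0,0.548000561822,0,0,0,3e-09,variable,predictive,True,17
ExpI,4,82.857143,0,0.846296307442,0,5.55111512313e-14,0,3e-09,variable,predictive,True,17
ExpI,4,114.285714,0,1.15731428051,0,1.80667980576e-09,0,3e-09,variable,predictive,True,16.9999999998
ExpI,4,145.714286,0,1.51989548685,0,0.000148440667258,0,3e-09,variable,predictive,True,16.9999843119
ExpI,4,177.142857,0,1.87012023448,0,0.651730368358,0,3e-09,variable,predictive,True,16.943341505
ExpI,4,208.571429,0,1.98978682939,0,19.4775752598,0,3e-09,variable,predictive,True,15.5618612219
ExpI,4,240,0,2.06397385798,0,48.7817040867,0,3e-09,variable,predictive,True,13.869840651
ExpI,4,0,100,0,0.940207440811,0,11.1234894344,8e-10,variable,predictive,True,17
ExpI,4,20,100,0.210998072035,0.905465993194,8.77830097466e-05,16.173762853,1.22378347985e-09,variable,predictive,True,16.9999324071
ExpI,4,51.428571,100,0.496052343602,0.806002009321,3.10068052,22.4457457236,1.6446103239e-09,variable,predictive,True,16.0715184366
ExpI,4,82.857143,100,0.598749371552,0.764724112166,24.0749219792,24.894178168,1.76588824133e-09,variable,predictive,True,12.5253851985
ExpI,4,114.285714,100,0.683128408715,0.776146267005,50.5962079345,26.0727991974,1.81816789933e-09,variable,predictive,True,10.1821609638
ExpI,4,145.714286,100,0.699683024295,0.773017083383,78.6103599532,26.9039468899,1.85298615728e-09,variable,predictive,True,8.69196393496
ExpI,4,177.142857,100,0.738661031474,0.75061791985,107.36393791,27.5614051508,1.87942838927e-09,variable,predictive,True,7.66626409996
ExpI,4,208.571429,100,0.729278791649,0.749119535045,136.578819563,28.1096352081,1.90078167073e-09,variable,predictive,True,6.91561868587
ExpI,4,240,100,0.762918278235,0.763812770152,166.115020431,28.5812416165,1.91867015496e-09,variable,predictive,True,6.34095285565
ExpI,6,0,0,0,0,0,0,3e-09,variable,predictive,True,17
ExpI,6,20,0,0.205101338816,0,0,0,3e-09,variable,predictive,True,17
ExpI,6,51.428571,0,0.545389957002,0,1.11022302463e-13,0,3e-09,variable,predictive,True,17
ExpI,6,82.857143,0,0.83753758568,0,3.41668360271e-09,0,3e-09,variable,predictive,True,16.9999999994
ExpI,6,114.285714,0,1.17775716995,0,0.000244691158099,0,3e-09,variable,predictive,True,16.9999670279
ExpI,6,145.714286,0,1.49683776163,0,2.48704060383,0,3e-09,variable,predictive,True,16.7371539386
ExpI,6,177.142857,0,1.56074875561,0,25.2806692021,0,3e-09,variable,predictive,True,14.8022127873
ExpI,6,208.571429,0,1.60843016494,0,53.3790642778,0,3e-09,variable,predictive,True,13.0587238894
ExpI,6,240,0,1.63298649003,0,82.5345865717,0,3e-09,variable,predictive,True,11.7040306933
ExpI,6,0,100,0,0.707371505176,0,31.1677744578,8e-10,variable,predictive,True,17
ExpI,6,20,100,0.206536439252,0.622051834095,1.2569310176e-08,39.7393385157,1.34821377205e-09,variable,predictive,True,16.9999999903
ExpI,6,51.428571,100,0.538631303752,0.489969208627,5.36487583525e-06,54.0165986921,1.96148814102e-09,variable,predictive,True,16.9999983935
ExpI,6,82.857143,100,0.86371321647,0.358185164669,0.0347922056634,65.054649905,2.34719138076e-09,variable,predictive,True,16.9935334487
ExpI,6,114.285714,100,1.14055581573,0.284307226904,5.71427757033,73.1822014389,2.56422564291e-09,variable,predictive,True,16.2300010955
ExpI,6,145.714286,100,1.23919617353,0.251254947193,27.2842543923,76.0793033891,2.63031075989e-09,variable,predictive,True,14.1164288062
ExpI,6,177.142857,100,1.33178125381,0.2341166626,53.3945679463,77.587443345,2.66264819828e-09,variable,predictive,True,12.3581173958
ExpI,6,208.571429,100,1.31179066721,0.2185988302,80.9454791734,78.6614003623,2.68485844873e-09,variable,predictive,True,11.0233406596
ExpI,6,240,100,1.39468502076,0.211474766357,109.246203499,79.5112808403,2.70196751916e-09,variable,predictive,True,9.99003527548
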