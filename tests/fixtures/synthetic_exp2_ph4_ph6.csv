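design_id,pH,HA_added_mg_L,FA_added_mg_L,HA_ads_mg_m2,FA_ads_mg_m2,HA_sol_mg_L,FA_sol_mg_L,V_m3_m2,scenario,mode,converged,M_w_HA_ads_kDa
ExpII,4,0,0,0,0,0,0,3e-09,variable,predictive,True,17
ExpII,4,0,25,0,0.255427467849,0,1.21430643318e-13,8e-10,variable,predictive,True,17
ExpII,4,0,50,0,0.533449942283,0,9.92608079065e-09,8e-10,variable,predictive,True,17
ExpII,4,0,75,0,0.774366930379,0,0.00152927003701,8e-10,variable,predictive,True,17
ExpII,4,0,100,0,0.918619542524,0,11.1234894448,8e-10,variable,predictive,True,17
ExpII,4,0,125,0,0.912773061571,0,34.8705604484,8e-10,variable,predictive,True,17
ExpII,4,0,150,0,0.904777306329,0,59.3367936195,8e-10,variable,predictive,True,17
ExpII,4,0,175,0,0.959890529779,0,84.0048750102,8e-10,variable,predictive,True,17
ExpII,4,0,200,0,0.928195085626,0,108.767058188,8e-10,variable,predictive,True,17
ExpII,4,160,0,1.69160005448,0,0.00895934266174,0,3e-09,variable,predictive,True,16.9991376633
ExpII,4,160,25,1.55352843386,0.269939016523,12.7454208273,0.00958381171238,2.68080979364e-09,variable,predictive,True,15.7732532454
ExpII,4,160,50,1.12055058464,0.513419763644,50.8303798372,0.598278366888,2.31460636984e-09,variable,predictive,True,12.1075759407
ExpII,4,160,75,0.813113908732,0.676319937226,80.1725400159,8.57661423429,2.00081638547e-09,variable,predictive,True,9.28339302347
ExpII,4,160,100,0.73354411985,0.764109213113,91.6101305779,27.2193172417,1.8657868118e-09,variable,predictive,True,8.18252493188
ExpII,4,160,125,0.656880608357,0.800613019888,97.0010901592,49.2944909234,1.79922989283e-09,variable,predictive,True,7.66364507218
ExpII,4,160,150,0.631856005391,0.80278842813,100.310606357,72.5266754802,1.75737870883e-09,variable,predictive,True,7.34510413816
ExpII,4,160,175,0.581061359578,0.82010685105,102.639051076,96.2972323744,1.72746318293e-09,variable,predictive,True,7.12099133393
ExpII,4,160,200,0.574001972485,0.85162578311,104.410659412,120.370464577,1.70443400287e-09,variable,predictive,True,6.95047403157
ExpII,6,0,0,0,0,0,0,3e-09,variable,predictive,True,17
ExpII,6,0,25,0,0.264114469336,0,5.70478178585e-08,8e-10,variable,predictive,True,17
ExpII,6,0,50,0,0.511727856603,0,0.00786110628524,8e-10,variable,predictive,True,17
ExpII,6,0,75,0,0.687297868117,0,8.94849761849,8e-10,variable,predictive,True,17
ExpII,6,0,100,0,0.725648212146,0,31.1677744497,8e-10,variable,predictive,True,17
ExpII,6,0,125,0,0.726878547375,0,54.9227197752,8e-10,variable,predictive,True,17
ExpII,6,0,150,0,0.72925250677,0,79.1270843658,8e-10,variable,predictive,True,17
ExpII,6,0,175,0,0.732931797579,0,103.544726221,8e-10,variable,predictive,True,17
ExpII,6,0,200,0,0.739630142706,0,128.086507065,8e-10,variable,predictive,True,17
ExpII,6,160,0,1.56198628991,0,11.292919488,0,3e-09,variable,predictive,True,15.9130564883
ExpII,6,160,25,1.35497912574,0.155689560329,28.790308403,9.91772650219,2.773186438e-09,variable,predictive,True,14.2289328162
ExpII,6,160,50,1.3199540879,0.205147349583,33.9706642151,30.747008716,2.70845331515e-09,variable,predictive,True,13.7303235693
ExpII,6,160,75,1.28414422923,0.220916746686,36.8620859379,53.4468654308,2.67228866954e-09,variable,predictive,True,13.4520242285
ExpII,6,160,100,1.27229279816,0.245478966578,38.8882974853,76.8447480272,2.64689381209e-09,variable,predictive,True,13.257001367
ExpII,6,160,125,1.25085289087,0.256182696944,40.4559354149,100.610157575,2.62720630288e-09,variable,predictive,True,13.1061162163
ExpII,6,160,150,1.27273620083,0.265288113372,41.738140691,124.603324664,2.61107298026e-09,variable,predictive,True,12.9827039585
ExpII,6,160,175,1.20437180441,0.268893473981,42.8249816643,148.751871494,2.5973740363e-09,variable,predictive,True,12.8780955148
ExpII,6,160,200,1.23977325021,0.278542895282,43.7694125546,173.013389476,2.58545102128e-09,variable,predictive,True,12.7871940416
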