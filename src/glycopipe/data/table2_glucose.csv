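group,drug,n_discovery,mean_delta_discovery,ci_low_discovery,ci_high_discovery,p_discovery,n_replication,mean_delta_replication,ci_low_replication,ci_high_replication,p_replication
glucose_decreasing,GLYBURIDE,8345,-43.1949,-45.2227,-41.1672,<0.0001,651,-6.447095,-15.00825,2.11406,1.3970E-01
glucose_decreasing,GLIPIZIDE,7161,-34.9926,-37.0172,-32.968,<0.0001,1117,-9.768414,-15.729241,-3.807587,<0.0001
glucose_decreasing,METFORMIN,22601,-31.7508,-32.7881,-30.7135,<0.0001,4381,-14.96459,-17.66529,-12.26389,<0.0001
glucose_decreasing,INSULIN,7786,-28.6124,-31.0302,-26.1945,<0.0001,4575,-5.448993,-8.83992,-2.058065,0.0016
glucose_decreasing,PIOGLITAZONE,404,-14.5794,-20.8713,-8.2876,<0.0001,100,-9.562057,-26.886532,7.762418,0.2761
glucose_decreasing,LIRAGLUTIDE,84,-28.9598,-46.5825,-11.3372,0.0016,52,-12.48878,-37.15229,12.17472,0.3142
glucose_decreasing,GLIMEPIRIDE,85,-23.4793,-39.7981,-7.1605,0.0053,703,-17.82565,-25.971571,-9.679738,<0.0001
glucose_decreasing,SITAGLIPTIN,85,-9.3883,-22.9627,4.1862,0.1727,77,-26.36202,-42.86386,-9.86019,0.0021
experimental,SIMVASTATIN,136659,0.4508,0.3568,0.5448,<0.0001,3498,0.734901,-1.813262,3.283064,0.5718
experimental,FOSINOPRIL,12212,-0.8226,-1.2394,-0.4059,0.0001,73,1.121298,-12.3272,14.5698,0.8685
experimental,ROSUVASTATIN,6573,0.9923,0.4779,1.5066,0.0002,1411,2.51068,-1.169198,6.190559,0.1810
experimental,LISINOPRIL,97335,-0.2488,-0.3842,-0.1134,0.0003,6616,1.067576,-0.902239,3.037391,0.9020
experimental,PRAVASTATIN,14954,0.5336,0.2456,0.8215,0.0003,1660,3.462117,-0.7322978,7.6565323,0.1056
experimental,VERAPAMIL,4583,-0.9979,-1.6193,-0.3764,0.0017,715,-2.061128,-6.49482,2.372563,0.3617
experimental,TOPIRAMATE,4032,0.8667,0.3142,1.4193,0.0021,405,1.433802,-4.608238,7.475842,0.6411
experimental,SILDENAFIL,38485,0.3159,0.0942,0.5375,0.0052,461,6.203665,-1.884591,14.29192,0.1324
experimental,ATORVASTATIN,5771,0.8247,0.1841,1.4652,0.0116,2829,-1.437549,-4.506864,1.631767,0.3585
experimental,ASPIRIN,29834,-0.297,-0.5489,-0.0452,0.0208,11303,-0.3833803,-0.9497342,1.7164947,0.5730
experimental,BENAZEPRIL,2616,-0.8457,-1.7148,0.0233,0.0565,368,1.318718,-5.138851,7.776286,0.6882
experimental,OXCARBAZEPINE,329,2.2351,-0.0953,4.5654,0.0601,376,-12.84378,-22.936732,-2.750834,0.0128
experimental,ENALAPRIL,2989,-0.6762,-1.4181,0.0656,0.0740,922,1.31505,-2.504694,5.134793,0.4994
experimental,LOVASTATIN,14595,0.2771,-0.0312,0.5854,0.0781,770,3.966773,-1.025044,8.958589,0.1192
experimental,PREGABALIN,1220,1.1228,-0.1441,2.3898,0.0823,400,-4.517374,-13.390553,4.355804,0.3175
experimental,DABIGATRAN ETEXILATE,831,1.2539,-0.4717,2.9795,0.1542,52,2.301677,-9.122465,13.725818,0.6876
experimental,LEVETIRACETAM,1410,0.6273,-0.3889,1.6435,0.2261,947,-4.81774,-10.3211268,0.6856466,0.0861
experimental,DOFETILIDE,165,1.7798,-1.2467,4.8063,0.2473,52,-3.194277,-17.53305,11.14449,0.6566
experimental,DIPYRIDAMOLE,1326,-0.7342,-1.9806,0.5121,0.2480,70,5.131848,-3.252576,13.516272,0.2262
experimental,SALMON CALCITONIN,723,0.8165,-0.615,2.2481,0.2632,72,-0.4615575,-11.11558,10.19246,0.9314
experimental,LAMOTRIGINE,2340,0.4208,-0.343,1.1845,0.2801,467,2.711233,-3.841852,9.264317,0.4166
experimental,ISOSORBIDE,1259,0.7299,-0.8707,2.3304,0.3711,1250,0.5219031,-3.957712,5.001518,0.8192
experimental,PROPAFENONE,296,0.8757,-1.3405,3.092,0.4374,109,-2.98408,-11.335945,5.367785,0.4803
experimental,SULINDAC,2637,0.255,-0.4727,0.9827,0.4920,64,-0.8106771,-19.34646,17.7251,0.9306
experimental,PRILOCAINE,308,-0.8119,-3.2941,1.6703,0.5203,746,1.971907,-2.234013,6.177827,0.3577
experimental,FLUVASTATIN,1802,0.2088,-0.4771,0.8946,0.5506,39,1.08315,-14.09033,16.25663,0.8859
experimental,PENTOXIFYLLINE,805,-0.3254,-1.9554,1.3046,0.6953,105,6.625918,-12.57929,25.83113,0.4954
experimental,DICLOFENAC,10685,-0.0725,-0.4498,0.3048,0.7065,1328,0.446702,-3.445042,4.338445,0.8219
experimental,RAMIPRIL,526,0.399,-1.7078,2.5057,0.7100,482,-1.003529,-6.855517,4.848459686,0.7363
experimental,MICONAZOLE,1803,0.1451,-0.8235,1.1136,0.7690,80,-6.841524,-17.091672,3.408624,0.1878
experimental,PHENYTOIN,2682,-0.0855,-0.9099,0.7389,0.8388,254,2.698407,-3.767747,9.164561,0.4119
experimental,ISOSORBIDE DINITRATE,1469,0.1244,-1.1109,1.3597,0.8434,1256,-0.2453867,-4.74463,4.253856,0.9148
experimental,LIDOCAINE,1841,0.093,-0.8702,1.0561,0.8499,6143,1.984721,0.1399591,3.8294838,0.0350
experimental,MINOXIDIL,218,-0.3757,-4.649,3.8975,0.8626,415,-1.185078,-9.736265,7.36611,0.7855
experimental,PRIMIDONE,882,-0.1221,-1.5594,1.3151,0.8676,125,-1.1066,-11.644133,9.430933,0.8357
glucose_increasing,ATENOLOL,25545,0.5676,0.3127,0.8225,<0.0001,568,1.460915,-3.094773,6.016604,0.5290
glucose_increasing,PROPRANOLOL,8806,0.9974,0.5079,1.487,<0.0001,171,1.122807,-9.919777,12.165391,0.8412
glucose_increasing,RISPERIDONE,5015,1.2782,0.6408,1.9156,<0.0001,52,-20.94231,-55.2099,13.32529,0.2255
glucose_increasing,CARVEDILOL,2540,2.0708,1.054,3.0876,<0.0001,805,4.463354,-2.046625,10.973333,0.1787
glucose_increasing,HYDROCHLOROTHIAZIDE,55715,2.1662,2.0019,2.3305,<0.0001,1731,0.5670133,-1.625194,2.759221,0.6120
glucose_increasing,PREDNISONE,10064,3.3271,2.8554,3.7988,<0.0001,1058,1.359641,-2.993715,5.712997,0.5401
glucose_increasing,DEXAMETHASONE,814,11.0592,8.9244,13.1941,<0.0001,804,4.72236,1.306546,8.138174,0.0068
glucose_increasing,OLANZAPINE,2855,1.8426,0.906,2.7792,0.0001,58,-4.568966,-13.350344,4.212413,0.3019
glucose_increasing,AMITRIPTYLINE,10722,0.7722,0.3477,1.1967,0.0004,204,-2.529412,-10.320404,5.261581,0.5228
glucose_increasing,METOPROLOL,20349,0.5649,0.2479,0.8819,0.0005,1726,4.256833,1.197392,7.316273,<0.0001
glucose_increasing,NORTRIPTYLINE,3569,0.9445,0.2535,1.6356,0.0074,56,-7.928571,-27.27985,11.42271,0.4151
glucose_increasing,METHYLPREDNISOLONE,329,3.8446,0.8012,6.888,0.0135,35,20.8881,11.4221464,30.354045,0.0005
glucose_increasing,HYDROCORTISONE,674,1.778,0.3158,3.2402,0.0172,97,8.06701,-0.3042293,16.43825,0.0588
glucose_increasing,QUETIAPINE,7939,0.5904,0.0905,1.0903,0.0206,30,-13.93333,-45.70653,17.83987,0.3772
glucose_increasing,NADOLOL,383,2.4766,0.2753,4.678,0.0276,59,-9.339266,-26.89005,8.21152,0.2912
glucose_increasing,BISOPROLOL,130,3.742,-0.1533,7.6373,0.0596,33,-2.742424,-20.8768,15.39195,0.7600
glucose_increasing,PAROXETINE,7083,0.5042,-0.0618,1.0702,0.0808,108,1.62037,-8.661824,11.902565,0.7553
glucose_increasing,LEVOFLOXACIN,420,-1.6014,-3.4438,0.241,0.0883,202,2.534653,-6.477816,11.547123,0.5798
glucose_increasing,DOXEPIN,1881,0.7812,-0.3126,1.8751,0.1615,36,5.777778,-14.16079,25.71634,0.5601
glucose_increasing,CIPROFLOXACIN,800,0.7613,-0.8172,2.3397,0.3441,142,10.5979,-7.865984,29.061789,0.2584
glucose_increasing,SERTRALINE,32238,0.1053,-0.1203,0.3309,0.3602,248,4.165323,-4.117053,12.447698,0.3229
glucose_increasing,EZETIMIBE,954,-0.52,-1.7218,0.6818,0.3961,145,6.453448,-3.820649,16.727546,0.2164
glucose_increasing,CITALOPRAM,30433,-0.0787,-0.3139,0.1565,0.5118,389,-3.589974,-9.485146,2.305198,0.2319
glucose_increasing,FLUOXETINE,15757,0.0989,-0.2237,0.4214,0.5480,207,-1.070048,-8.646338,6.506242,0.7809
glucose_increasing,SOTALOL,723,0.4891,-1.1468,2.1251,0.5574,55,-2.490909,-14.862197,9.880378,0.6880
glucose_increasing,MOXIFLOXACIN,126,-0.6569,-4.3452,3.0313,0.7250,140,-0.2695035,-9.122082,8.583075,0.9521
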