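group,drug,n_discovery,mean_delta_discovery,ci_low_discovery,ci_high_discovery,p_discovery,n_replication,mean_delta_replication,ci_low_replication,ci_high_replication,p_replication
glucose_decreasing,GLYBURIDE,7639,-1.1525,-1.1979,-1.107,<0.0001,225,-0.7408889,-0.9785815,-0.5031962,<0.0001
glucose_decreasing,GLIPIZIDE,7564,-1.0307,-1.0741,-0.9873,<0.0001,429,-0.6013986,-0.7672611,-0.4355361,<0.0001
glucose_decreasing,METFORMIN,25589,-0.9612,-0.983,-0.9393,<0.0001,1732,-0.776097,-0.8561348,-0.6960592,<0.0001
glucose_decreasing,LIRAGLUTIDE,112,-0.8491,-1.1336,-0.5646,<0.0001,34,-0.4264706,-0.89595328,0.04301211,0.0736
glucose_decreasing,GLIMEPIRIDE,109,-0.8179,-1.1233,-0.5125,<0.0001,302,-0.7006623,-0.878078,-0.5232465,<0.0001
glucose_decreasing,INSULIN,8614,-0.7853,-0.8265,-0.7441,<0.0001,1558,-0.7970475,-0.8950016,-0.6990934,<0.0001
glucose_decreasing,PIOGLITAZONE,498,-0.4414,-0.5679,-0.3149,<0.0001,30,-0.24,-0.53962488,0.05962488,0.1122
glucose_decreasing,SITAGLIPTIN,103,-0.0777,-0.2962,0.1409,0.4825,35,-0.4257143,-0.9284599,0.0770313,0.0944
experimental,LISINOPRIL,17374,-0.0346,-0.0455,-0.0237,<0.0001,1145,-0.2383406,-0.3156355,-0.1610457,<0.0001
experimental,BENAZEPRIL,579,-0.0813,-0.1321,-0.0306,0.0017,68,-0.3191176,-0.62066544,-0.01756986,0.0384
experimental,PRAVASTATIN,3944,-0.0253,-0.0447,-0.00592,0.0105,284,-0.251669,-0.40619831,-0.09713972,0.0015
experimental,VERAPAMIL,522,-0.0665,-0.1231,-0.0099,0.0214,81,-0.2185185,-0.4354824,-0.00155464,0.0484
experimental,ISOSORBIDE DINITRATE,157,0.1231,0.0089,0.2372,0.0348,177,-0.01299435,-0.1621161,0.1361274,0.8637
experimental,ENALAPRIL,577,-0.0426,-0.0898,0.00461,0.0768,123,0.06910569,-0.1325936,0.270805,0.4989
experimental,ROSUVASTATIN,2149,0.0277,-0.00453,0.0599,0.0920,285,-0.08736842,-0.20676963,0.03203279,0.1509
experimental,ISOSORBIDE,357,0.0604,-0.0232,0.1441,0.1563,171,-0.01169591,-0.1657714,0.1423795,0.8811
experimental,ASPIRIN,3928,-0.0174,-0.0431,0.00824,0.1833,1834,-0.1676521,-0.2182151,-0.1170891,<0.0001
experimental,TOPIRAMATE,739,-0.0242,-0.0612,0.0128,0.1992,53,-0.3113208,-0.70960458,0.08696307,0.1228
experimental,LOVASTATIN,1844,-0.0153,-0.0436,0.013,0.2880,172,-0.2290698,-0.38846987,-0.06966967,0.0051
experimental,SILDENAFIL,8563,-0.00697,-0.0215,0.00759,0.3479,51,-0.6882353,-1.2261789,-0.1502917,0.0132
experimental,OXCARBAZEPINE,52,0.0404,-0.0603,0.141,0.4242,39,-0.2923077,-0.7680527,0.1834373,0.2212
experimental,LAMOTRIGINE,402,0.0247,-0.0386,0.088,0.4434,46,-0.273913,-0.7942324,0.2464063,0.2947
experimental,PRILOCAINE,74,0.0514,-0.0881,0.1908,0.4655,127,0.0247244,-0.1739227,0.2148676,0.8352
experimental,LEVETIRACETAM,193,0.0254,-0.0456,0.0964,0.4817,75,-0.02666667,-0.3173848,0.2640514,0.8555
experimental,LIDOCAINE,331,0.0173,-0.0351,0.0697,0.5160,567,-0.1074074,-0.19241439,-0.02240043,0.0134
experimental,SIMVASTATIN,21353,0.00255,-0.00649,0.0116,0.5802,561,-0.142246,-0.28449198,-0.03422388,0.0099
experimental,ATORVASTATIN,2328,0.00881,-0.0294,0.047,0.6512,619,-0.1924071,-0.2966929,-0.0881213,0.0003
experimental,DICLOFENAC,2012,-0.00398,-0.0307,0.0228,0.7703,238,-0.04453782,-0.17240455,0.08332892,0.4933
experimental,RAMIPRIL,102,0.0167,-0.1017,0.135,0.7806,96,-0.146875,-0.35919937,0.06544937,0.1729
experimental,PREGABALIN,322,0.0027,-0.0835,0.0889,0.9508,36,-0.05277778,-0.4503729,0.3448173,0.7891
glucose_increasing,HYDROCHLOROTHIAZIDE,6016,0.1028,0.085,0.1205,<0.0001,664,0.05406627,-0.01880839,0.12694092,0.1457
glucose_increasing,PROPRANOLOL,1088,0.1415,0.0921,0.1909,<0.0001,94,0.09893617,-0.08261529,0.28048763,0.2820
glucose_increasing,PREDNISONE,829,0.2814,0.2088,0.3539,<0.0001,412,0.008009709,-0.1028593,0.1188787,0.8871
glucose_increasing,NORTRIPTYLINE,499,0.1074,0.0428,0.1721,0.0012,32,0.046875,-0.2186954,0.3124454,0.7213
glucose_increasing,METOPROLOL,3259,0.0385,0.014,0.063,0.0021,520,-0.02230769,-0.13145947,0.08684408,0.6882
glucose_increasing,ATENOLOL,2873,0.0401,0.0136,0.0666,0.0030,240,0.1520833,-0.006750816,0.310917483,0.0605
glucose_increasing,QUETIAPINE,1248,0.0493,0.0148,0.0839,0.0052,36,0.02222222,-0.2910418,0.3354863,0.8863
glucose_increasing,AMITRIPTYLINE,1269,0.0523,0.00909,0.0956,0.0177,141,0.1815603,0.02675168,0.33636889,0.0219
glucose_increasing,CITALOPRAM,3754,-0.0237,-0.0447,-0.00264,0.0274,339,-0.007079646,-0.1371858,0.1230265,0.9148
glucose_increasing,OLANZAPINE,292,0.104,-0.00161,0.2096,0.0536,54,0.011111,-0.1708453,0.1930675,0.9030
glucose_increasing,FLUOXETINE,2318,-0.0207,-0.047,0.00566,0.1239,176,0.009659091,-0.1351066,0.1544248,0.8954
glucose_increasing,PAROXETINE,1000,0.0381,-0.0112,0.0874,0.1297,55,-0.009090909,-0.2567106,0.2385288,0.9416
glucose_increasing,CARVEDILOL,655,0.0371,-0.0271,0.1014,0.2565,247,0.1809717,0.0079371,0.3540062,0.0405
glucose_increasing,CIPROFLOXACIN,54,-0.1167,-0.3366,0.1033,0.2922,182,0.1961538,0.01111352,0.38119418,0.0379
glucose_increasing,RISPERIDONE,643,0.0227,-0.0293,0.0747,0.3914,47,-0.3808511,-0.8242209,0.0625188,0.0905
glucose_increasing,EZETIMIBE,194,-0.0299,-0.1196,0.0598,0.5117,80,0.1925,-0.1369853,0.5219853,0.2484
glucose_increasing,SERTRALINE,5519,0.00351,-0.014,0.021,0.6937,151,-0.1264901,-0.29593777,0.04295764,0.1423
glucose_increasing,HYDROCORTISONE,54,0.0278,-0.1555,0.2111,0.7624,58,0.2448276,-0.1630528,0.652708,0.2343
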