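sample_id,1100,1145.1,1190.19,1235.29,1280.39,1325.48,1370.58,1415.68,1460.77,1505.87,1550.97,1596.06,1641.16,1686.26,1731.35,1776.45,1821.55,1866.65,1911.74,1956.84,2001.94,2047.03,2092.13,2137.23,2182.32,2227.42,2272.52,2317.61,2362.71,2407.81,2452.9,2498,target:moisture,target:oil,target:protein,target:starch
S000,0.449020792797,0.508302679654,0.531254431766,0.522653665502,0.532275245396,0.560631383727,0.595437466649,0.629083906754,0.663019561242,0.701516607914,0.730458681988,0.742915155664,0.768669046044,0.840676083933,0.981747343763,1.19134236091,1.39107633943,1.45219512486,1.34744154148,1.17493071334,1.02929506345,0.939111862106,0.882556650883,0.850047657407,0.843931998563,0.84204163879,0.811836375755,0.780283455835,0.763387742905,0.748696858139,0.726527997254,0.693023810001,10.2304674583,3.55377419675,8.53293107232,64.4579616878
S001,0.457046959904,0.517489088991,0.540670024675,0.531935796197,0.541385651028,0.570402965533,0.605598772898,0.639836560175,0.67361558505,0.712156209673,0.740894541309,0.753698295671,0.780353466082,0.85307608259,0.996315936263,1.21064781997,1.41485904313,1.47847721397,1.37217060683,1.19634940521,1.04808157291,0.955802575906,0.897616226071,0.86365298729,0.857044319431,0.855023803685,0.824049480296,0.791723107667,0.774530743197,0.759453069227,0.737048964994,0.703294616641,10.0572251016,3.3215036201,8.7000718013,65.5896327027
S002,0.458086802492,0.519037779628,0.542027746008,0.532015044936,0.541029874975,0.569847718449,0.604804003178,0.639085689726,0.672396162295,0.710547914359,0.738973315289,0.751752264449,0.777875023187,0.849820497132,0.99177816542,1.20348445763,1.40525241207,1.4676906626,1.36230478336,1.18831011311,1.04185202698,0.950470536631,0.89299844252,0.859584488221,0.853830926524,0.852142941981,0.821180614344,0.788520295358,0.771283113386,0.756290831823,0.73374603452,0.700269427895,10.042961523,3.38831451803,8.91492102509,64.9394085357
S003,0.452844416085,0.51273571817,0.535714811822,0.527059084492,0.536442314456,0.565119632972,0.600377572238,0.634139514236,0.668107298128,0.706817797747,0.735867744027,0.748097390543,0.774333672386,0.84647454199,0.987837017123,1.19911867997,1.40026825161,1.4624767719,1.35710328841,1.18359054268,1.03723551925,0.946394985096,0.889127305194,0.856036173586,0.850297627721,0.848216930254,0.81769982966,0.78582708564,0.76873646146,0.75400933662,0.731699640211,0.697965596466,10.2700574146,3.33251575195,8.65537408877,65.1421747278
S004,0.449128226669,0.505362300594,0.528799448464,0.523760774981,0.534989865608,0.563282796827,0.597349195567,0.630954683723,0.66472818422,0.702809267476,0.731727310482,0.744911019698,0.771495350285,0.844049363772,0.987342467592,1.20291052606,1.40862593842,1.47318889803,1.36676540625,1.19059115775,1.04196528678,0.949223790708,0.890182748284,0.85521141622,0.846679184271,0.84258242514,0.813587449981,0.783640578195,0.766672297736,0.75183925673,0.729884850976,0.696953944104,9.71919847203,3.41762916301,7.7193886301,65.977352012
S005,0.454555063339,0.512184465165,0.535408705263,0.529145209834,0.539992122804,0.568429385684,0.602803438849,0.636464710666,0.66980181299,0.70742080256,0.735820913723,0.749158200681,0.775866905636,0.848611441974,0.993005386161,1.21008381447,1.41811412929,1.48322476134,1.37634651832,1.19848891002,1.04874162519,0.954995865546,0.895412400942,0.85975178499,0.851098026645,0.847451694319,0.817459109082,0.786571945591,0.76936873483,0.754410070336,0.731899212914,0.698733777413,9.53014068564,3.45768359641,8.03627675928,66.3596775691
S006,0.448428352143,0.503273034738,0.526558492654,0.523091629687,0.535167688487,0.563442148811,0.597388305595,0.631048153042,0.666050775052,0.70570165022,0.735346165213,0.748113460299,0.774523821987,0.847627809255,0.991020034829,1.20508650644,1.40905098984,1.47219463301,1.36536731051,1.18964118192,1.04112500893,0.949199649335,0.891320460916,0.857124369759,0.848867221085,0.844833710315,0.816174008748,0.786920373153,0.770505601839,0.755630413758,0.733565177143,0.699919158238,10.2895654129,3.46635242997,7.41162014459,65.8267287263
S007,0.451258700472,0.508115059831,0.531435901713,0.525660207975,0.536684140245,0.565077943698,0.59948231147,0.633385624263,0.667575284368,0.706748816811,0.735912979012,0.748956948255,0.775226029103,0.847983576251,0.990821710054,1.20395208152,1.40702900706,1.46947514801,1.36318164348,1.18811658088,1.04055422865,0.9488072091,0.891112440726,0.857348716153,0.849787945884,0.846839939373,0.817363533413,0.786905112077,0.770177197074,0.75543183389,0.733148167927,0.699651289077,10.2115696407,3.52039561748,7.90493211725,65.3410609266
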