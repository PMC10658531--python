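device,taking_measurement,point_cloud,point_cloud_2,final_points,triangles,height_cm,width_cm,length_cm,top_ledge,bottom_ledge,measure_time_min,design_time_min,manufacturing_time_min,postprocessing_time_min,total_time_min
1,manual,,,,,2,6,9,1.5,1,4.5,60,390,70,524.5
2,manual,,,,,2,3,8,1.5,1,4,65,325,65,459
3,manual,,,,,1,1,1,0.3,0.3,6,20,45,60,131
4,manual,,,,,1,1.5,1.5,1,1,7,5,40,60,112
5,scanner,162013,132639,427434,854864,1,1.3,2.2,1,1,20,60,38,60,178
6,scanner,196347,188527,492409,985218,1.5,0.8,0.8,0.3,0.2,35,60,18,70,183
7,scanner,221505,219614,506203,1012526,1.5,3.5,4.5,0.7,0.5,30,50,172,65,317
8,manual,,,,,2,2,3,0.7,0.3,2,45,115,65,227
9,manual,,,,,2.8,3,3,0.6-0.8,0.2-0.6,1,5,130,65,201
10,scanner,481104,349133,924731,1850126,1.5,3,3.5,0.7,0.3,25,25,153,65,268
11,scanner,355238,254712,930626,1861428,1.5,2,3,0.4-1,0.2-0.7,20,30,119,65,234
12,scanner,355238,254712,930626,1861428,1.5,1.5,1.5,1,0.5,15,15,110,60,200
13,scanner,227215,163856,431593,863462,1.5,3.5,4.8,1,1,20,55,130,60,265
14,scanner,234584,191531,707240,1414580,1.5,2.5,4.8,0.5,0.5,15,35,142,60,252
15,scanner,324733,233194,844528,1689296,2,4,5.2,1,0.5,15,20,240,60,335
16,scanner,324733,233194,844528,1689296,1.2,1.5,2,1,0.3,15,20,92,60,187
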