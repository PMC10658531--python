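patient,length_before,length_after,width_before,width_after,height_before,height_after,cures_before,cures_after,pruritus_before,pruritus_after,vas_before,vas_after,therapy_days,n_changes,solution,definitive_closure_surgery,survival_3_months
1,12,10,14,11,2,1,28,3,6,0,8,4,14,4,ostomization,no,no
2,16,16,13,8,6,2,28,3.5,7,0,6,0,8,3,closure,yes,yes
3,20,18,4,3,2,1,35,2.5,5,2,7,3,15,,closure,no,no
4,9,7.5,15,4,2,1,35,3.5,6,0,5,0,30,10,ostomization,yes,yes
5,16,9,15,7,2,0,14,2,5,0,0,0,29,8,ostomization,yes,yes
6,16,9,15,8,1.5,0,14,3,0,0,2,0,28,8,ostomization,pending,yes
7,8,5.5,13,7.5,2,0,28,2,5,0,8,0,50,23,ostomization,yes,yes
8,15,11,20,12,3,0,7,2,6,0,7,0,35,13,ostomization,pending,yes
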