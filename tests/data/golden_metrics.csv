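participant_id,trial_index,experiment,role,target_condition,wolf_behavior,wolf_speed,outcome,n_selected,n_cat_a,n_cat_b,n_runs,itt_mean,itd_mean,r1,r2,best_r,wolf_distance_mean,selection_order_high,selection_order_low,n_patches,n_selection_errors,duration_ms,points_earned
fix0,0,E1_avoid,distracted,feature,pack,54.000000,completed,40,20,20,18,1766.666667,440.331785,0.133017,-0.068075,0.133017,192.788518,17.000000,24.000000,,0,69866.666667,0
fix1,0,E1_avoid,hunted,conjunction,lone,78.000000,eaten,11,3,8,2,1995.000000,282.534756,0.247227,0.023803,0.247227,203.275240,2.000000,7.500000,,0,23650.000000,0
fix2,0,E3_reward,distracted,reward,lone,78.000000,completed,20,10,10,11,1386.842105,326.289313,-0.107696,-0.291836,0.291836,164.730987,9.200000,11.800000,,0,26733.333333,30
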