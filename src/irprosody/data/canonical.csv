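utterance,label,start,end,pitch,unit,break,break_level
fig3,Mar,0.0,0.3,10.0,st,,1
fig3,i,0.3,0.5700000000000001,11.0,st,,1
fig3,an,0.5700000000000001,1.245,12.5,st,,1
fig3,na,1.245,1.7175,8.5,st,,1
fig3,ma,1.7175,2.8987499999999997,9.5,st,,1
fig3,lade,2.8987499999999997,4.08,10.5,st,,1
fig3a,mar,0.0,0.3,12.5,st,,1
fig3a,ma,0.3,0.51,8.5,st,,1
fig3a,lade,0.51,1.0350000000000001,9.5,st,,1
case1_statement,Ma,0.0,0.2,10.0,st,,1
case1_statement,ri,0.2,0.4,11.0,st,,1
case1_statement,an,0.4,0.76,12.5,st,,1
case1_statement,na,0.76,1.1600000000000001,8.5,st,,1
case1_statement,made,1.1600000000000001,1.6600000000000001,11.5,st,,1
case1_statement,the,1.6600000000000001,2.21,11.0,st,,1
case1_statement,mar,2.21,3.08,10.2,st,,1
case1_statement,ma,3.08,3.58,12.6,st,,1
case1_statement,lade,3.58,5.28,11.9,st,,1
case1_both_new,Ma,0.0,0.2,10.0,st,,1
case1_both_new,ri,0.2,0.4,11.0,st,,1
case1_both_new,an,0.4,0.76,12.5,st,,1
case1_both_new,na,0.76,1.1600000000000001,8.5,st,,1
case1_both_new,made,1.1600000000000001,1.6600000000000001,11.5,st,,1
case1_both_new,the,1.6600000000000001,2.21,11.0,st,,1
case1_both_new,mar,2.21,3.08,10.2,st,,1
case1_both_new,ma,3.08,3.58,13.4,st,,1
case1_both_new,lade,3.58,5.28,11.9,st,,1
case1_contrastive,Ma,0.0,0.2,10.0,st,,1
case1_contrastive,ri,0.2,0.4,10.25,st,,1
case1_contrastive,an,0.4,0.76,12.5,st,,1
case1_contrastive,na,0.76,1.1600000000000001,8.5,st,,1
case1_contrastive,made,1.1600000000000001,1.6600000000000001,11.5,st,,1
case1_contrastive,the,1.6600000000000001,2.21,11.0,st,,1
case1_contrastive,mar,2.21,3.08,10.2,st,,1
case1_contrastive,ma,3.08,3.58,12.6,st,,1
case1_contrastive,lade,3.58,5.28,11.9,st,,1
case1_question,Ma,0.0,0.2,10.0,st,,1
case1_question,ri,0.2,0.4,11.0,st,,1
case1_question,an,0.4,0.76,12.5,st,,1
case1_question,na,0.76,1.1600000000000001,8.5,st,,1
case1_question,made,1.1600000000000001,1.6600000000000001,11.5,st,,1
case1_question,the,1.6600000000000001,2.21,11.0,st,,1
case1_question,mar,2.21,3.08,10.2,st,,1
case1_question,ma,3.08,3.58,10.5,st,,1
case1_question,lade,3.58,5.28,11.9,st,,1
case2_suspend,you,0.0,0.3,10.0,st,,1
case2_suspend,want,0.3,0.6,12.0,st,,1
case2_suspend,ex,0.6,0.8999999999999999,13.0,st,,1
case2_suspend,am,0.8999999999999999,1.2,14.5,st,,1
case2_suspend,ple,1.2,1.5,13.5,st,...;#,1
case2_suspend,Mo,2.0,2.35,16.0,st,,1
case2_suspend,re,2.35,2.7,13.0,st,,1
case2_suspend,sa,2.7,3.5,12.2,st,,1
case2_halt,you,0.0,0.3,10.0,st,,1
case2_halt,want,0.3,0.6,12.0,st,,1
case2_halt,ex,0.6,0.8999999999999999,13.0,st,,1
case2_halt,am,0.8999999999999999,1.2,14.5,st,,1
case2_halt,ple,1.2,1.5,13.5,st,...;|,1
case2_halt,Mo,2.0,2.35,16.0,st,,1
case2_halt,re,2.35,2.7,13.0,st,,1
case2_halt,sa,2.7,3.5,12.2,st,,1
case3_bottom_up,The,0.0,0.2,9.5,st,,1
case3_bottom_up,Pen,0.2,0.55,12.0,st,,1
case3_bottom_up,ta,0.55,0.8,11.0,st,,1
case3_bottom_up,gon,0.8,1.1,10.5,st,- - -,1
case3_bottom_up,re,1.3,1.8,10.8,st,,1
case3_bottom_up,ports,1.8,2.25,13.0,st,- - -,1
case3_bottom_up,figh,2.55,2.9,12.0,st,,1
case3_bottom_up,ting,2.9,3.1999999999999997,11.2,st,,1
case3_bottom_up,six,3.1999999999999997,3.75,14.0,st,,1
case3_bottom_up,ties,3.75,4.55,11.5,st,,1
case3_annotated,The,0.0,0.2,9.5,st,,1
case3_annotated,Pen,0.2,0.55,12.0,st,,1
case3_annotated,ta,0.55,0.8,11.0,st,,1
case3_annotated,gon,0.8,1.1,10.5,st,- - -,1
case3_annotated,re,1.3,1.8,10.8,st,<,1
case3_annotated,ports,1.8,2.25,13.0,st,- - -;/,1
case3_annotated,figh,2.55,2.9,12.0,st,,1
case3_annotated,ting,2.9,3.1999999999999997,11.2,st,#,1
case3_annotated,six,3.1999999999999997,3.75,14.0,st,>,1
case3_annotated,ties,3.75,4.55,11.5,st,,1
case3_alternative,The,0.0,0.2,9.5,st,,1
case3_alternative,Pen,0.2,0.55,12.0,st,,1
case3_alternative,ta,0.55,0.8,11.0,st,,1
case3_alternative,gon,0.8,1.1,10.5,st,- - -,1
case3_alternative,re,1.3,1.8,10.8,st,<,1
case3_alternative,ports,1.8,2.25,13.0,st,- - -,1
case3_alternative,figh,2.55,2.9,12.0,st,,1
case3_alternative,ting,2.9,3.1999999999999997,11.2,st,#,1
case3_alternative,six,3.1999999999999997,3.75,14.0,st,>;/,1
case3_alternative,ties,3.75,4.55,11.5,st,,1
zoo_zero_initial,zer0,0.0,0.3,10.0,st,,1
zoo_zero_initial,zer1,0.3,0.6,10.05,st,,1
zoo_zero_initial,zer2,0.6,0.8999999999999999,13.0,st,,1
zoo_duplication,dup0,0.0,0.3,10.0,st,,1
zoo_duplication,dup1,0.3,0.6,10.1,st,,1
zoo_duplication,dup2,0.6,0.8999999999999999,10.05,st,,1
zoo_duplication,dup3,0.8999999999999999,1.2,11.0,st,,1
zoo_retro_L_then_P,ret0,0.0,0.3,10.0,st,,1
zoo_retro_L_then_P,ret1,0.3,0.6,14.5,st,,1
zoo_retro_L_then_P,ret2,0.6,0.8999999999999999,18.0,st,,1
zoo_retro_S_then_R,ret0,0.0,0.3,10.0,st,,1
zoo_retro_S_then_R,ret1,0.3,0.6,11.0,st,,1
zoo_retro_S_then_R,ret2,0.6,0.8999999999999999,10.5,st,,1
zoo_p_minus,p_m0,0.0,0.3,10.0,st,,1
zoo_p_minus,p_m1,0.3,0.6,12.5,st,,1
zoo_p_minus,p_m2,0.6,0.8999999999999999,12.8,st,,1
zoo_r_plus,r_p0,0.0,0.3,10.0,st,,1
zoo_r_plus,r_p1,0.3,0.6,6.0,st,,1
zoo_r_plus,r_p2,0.6,0.8999999999999999,12.0,st,,1
zoo_r_zero,r_z0,0.0,0.3,10.0,st,,1
zoo_r_zero,r_z1,0.3,0.6,13.0,st,,1
zoo_r_zero,r_z2,0.6,0.8999999999999999,10.0,st,,1
zoo_p_zero,p_z0,0.0,0.3,10.0,st,,1
zoo_p_zero,p_z1,0.3,0.6,11.0,st,,1
zoo_p_zero,p_z2,0.6,0.8999999999999999,12.0,st,,1
zoo_p_plus_descending,p_p0,0.0,0.3,10.0,st,,1
zoo_p_plus_descending,p_p1,0.3,0.6,9.5,st,,1
zoo_p_plus_descending,p_p2,0.6,0.8999999999999999,7.0,st,,1
zoo_overrides,ove0,0.0,0.3,10.0,st,,1
zoo_overrides,ove1,0.3,0.6,11.0,st,!],1
zoo_overrides,ove2,0.6,1.5,12.0,st,!x,1
zoo_overrides,ove3,1.5,2.4,13.0,st,,1
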