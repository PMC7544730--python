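id,name,source_region
0,kidney_other_tissue,kidneys
1,st0_rapid_soft_tissue,other_soft_tissue
2,st1_intermediate_soft_tissue,other_soft_tissue
3,st2_slow_soft_tissue,other_soft_tissue
4,trabecular_bone_volume,trabecular_bone
5,cortical_bone_volume,cortical_bone
6,trabecular_bone_surface,trabecular_bone
7,cortical_bone_surface,cortical_bone
8,trabecular_marrow,red_marrow
9,cortical_marrow,red_marrow
10,blood,blood
11,si_content,si_content
12,liver_1,liver
13,liver_2,liver
14,kidneys_urinary_path,kidneys
15,st_content,st_content
16,rc_content,rc_content
17,gonads,gonads
18,ub_content,ub_content
19,oesophagus_fast,oesophagus
20,oesophagus_slow,oesophagus
21,lc_content,lc_content
22,mouth,oral_cavity
23,rs_content,rs_content
24,urine,excreta
25,faeces,excreta
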