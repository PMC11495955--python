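cee_id,subspecies,metric,comparison,detected
2017_04,short_beaked,subgroups,post_vs_pre,0
2017_07,short_beaked,subgroups,post_vs_pre,1
2019_05,short_beaked,subgroups,post_vs_pre,1
2019_10,short_beaked,subgroups,post_vs_pre,0
2019_11,short_beaked,subgroups,post_vs_pre,0
2021_12,short_beaked,subgroups,post_vs_pre,0
2021_13,short_beaked,subgroups,post_vs_pre,1
2017_09,long_beaked,subgroups,post_vs_pre,0
2018_03,long_beaked,subgroups,post_vs_pre,0
2018_05,long_beaked,subgroups,post_vs_pre,0
2018_08,long_beaked,subgroups,post_vs_pre,1
2018_10,long_beaked,subgroups,post_vs_pre,1
2019_01,long_beaked,subgroups,post_vs_pre,1
2019_07,long_beaked,subgroups,post_vs_pre,0
2019_08,long_beaked,subgroups,post_vs_pre,1
2021_06,long_beaked,subgroups,post_vs_pre,0
2021_07,long_beaked,subgroups,post_vs_pre,1
2021_08,long_beaked,subgroups,post_vs_pre,1
2021_09,long_beaked,subgroups,post_vs_pre,1
2021_10,long_beaked,subgroups,post_vs_pre,1
2017_09,long_beaked,speed,exp_vs_pre,1
2018_03,long_beaked,speed,exp_vs_pre,1
2018_05,long_beaked,speed,exp_vs_pre,1
2018_08,long_beaked,speed,exp_vs_pre,1
2018_10,long_beaked,speed,exp_vs_pre,0
2019_01,long_beaked,speed,exp_vs_pre,0
2019_08,long_beaked,speed,exp_vs_pre,0
2021_06,long_beaked,speed,exp_vs_pre,1
2021_07,long_beaked,speed,exp_vs_pre,0
2021_08,long_beaked,speed,exp_vs_pre,0
2021_09,long_beaked,speed,exp_vs_pre,1
2021_10,long_beaked,speed,exp_vs_pre,0
2021_11,long_beaked,speed,exp_vs_pre,0
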