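trial_id,arm_id,drug_class,line,n,phase,controlled,median_os,q1_os,q3_os,median_pfs,q1_pfs,q3_pfs,hr_os,hr_pfs,orr_pct,os_rate_end_fu_pct,followup_mo
keynote240,pembrolizumab,ICI,second,278,III,true,13.9,6.15,24,3.0,1.46,8.45,0.781,0.718,18.3,,28
keynote224,pembrolizumab,ICI,second,104,I_II,false,12.9,7.25,16.1,4.9,2.12,12.5,,,17.3,,19
checkmate040_2017,nivolumab,ICI,second,182,I_II,false,15.1,,,4.0,,,,,14.3,,57
qin2020,camrelizumab,ICI,second,217,I_II,false,13.8,6.45,16.9,2.1,1.88,6.1,,,14.7,,22
sangro2013,tremelimumab,ICI,mixed,21,I_II,false,8.2,6,21.6,,,,,,17.6,,25
checkmate459,nivolumab,ICI,first,371,III,true,16.4,6.35,36.3,3.7,1.98,9.9,0.85,0.93,15.4,,39
checkmate459,sorafenib,MKI,first,372,III,true,14.7,6.0,27.3,3.8,1.95,7.65,,,7.0,,37
nct01693562,durvalumab,ICI,second,39,I_II,false,13.2,,,,,,,,10.3,,
checkmate040_2019,nivolumab_ipilimumab_a,ICI,second,50,I_II,false,23,,,,,,,,32,,37
checkmate040_2019,nivolumab_ipilimumab_b,ICI,second,49,I_II,false,12,,,,,,,,30.6,,37
checkmate040_2019,nivolumab_ipilimumab_c,ICI,second,49,I_II,false,13,,,,,,,,30.6,,37
nct02821754,tremelimumab_durvalumab,ICI,second,10,I_II,false,15.9,,,7.8,,,,,20,,
checkmate040_2020,nivolumab_ipilimumab_cabozantinib,ICI,mixed,35,I_II,false,24,9,NR,6.8,3.4,NR,,,31,,24
checkmate040_2020,nivolumab_cabozantinib,ICI,mixed,36,I_II,false,21.5,8.7,NR,5.4,2.73,NR,,,14,,24
imbrave150,atezolizumab_bevacizumab,ICI,first,336,III,true,NR,7.87,NR,6.8,2.9,13.5,0.58,0.59,26.5,,17
imbrave150,sorafenib,MKI,first,165,III,true,13.2,3.5,,4.3,1.17,7.3,,,11.9,,17
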