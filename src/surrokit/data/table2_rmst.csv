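trial_id,arm_id,drug_class,rmst6_pfs,rmst6_os,rmst12_pfs,rmst12_os
imbrave150,atezolizumab_bevacizumab,ICI,4.67,5.62,7.11,9.95
checkmate459,nivolumab,ICI,3.85,5.42,5.47,9.50
keynote240,pembrolizumab,ICI,3.65,5.37,5.19,9.23
keynote224,pembrolizumab,ICI,4.23,5.44,6.21,9.38
qin2020,camrelizumab,ICI,3.32,5.35,4.51,9.29
checkmate040_2020,nivolumab_ipilimumab_cabozantinib,ICI,4.72,5.37,7.17,9.76
checkmate040_2020,nivolumab_cabozantinib,ICI,4.44,5.62,6.6,10.13
sun1170,sorafenib,MKI,3.52,4.81,4.61,7.08
sun1170,sunitinib,MKI,3.68,5.00,4.54,7.76
sarah,sorafenib,MKI,3.91,5.21,5.22,8.54
sirvenib,sorafenib,MKI,4.48,5.28,6.16,8.63
calgb80802,sorafenib,MKI,3.68,5.00,4.75,8.03
silius,sorafenib,MKI,3.71,5.5,4.68,9.25
hsu2012,vandetanib,MKI,2.19,4.86,,
abou_alfa2010,sorafenib_doxorubicin,MKI,4.38,5.15,6.05,8.8
reflect,sorafenib,MKI,3.96,5.43,5.43,9.04
reflect,lenvatinib,MKI,4.85,5.54,7.78,9.29
imbrave150,sorafenib,MKI,3.96,5.25,5.28,8.56
checkmate459,sorafenib,MKI,4.02,5.40,5.35,9.25
zhu2013,cediranib,MKI,4.29,5.15,5.92,8.50
resorce,regorafenib,MKI,3.71,5.22,4.89,8.63
celestial,cabozantinib,MKI,4.19,5.30,5.29,8.76
reach,ramucirumab,MKI,3.31,5.17,4.39,8.18
reach2,ramucirumab,MKI,3.54,5.26,4.82,8.55
metiv_hcc,tivantinib,MKI,3.08,4.99,3.62,7.86
adi_peg20,adi_peg20,MKI,3.19,4.47,3.69,6.75
kang2015,axitinib,MKI,3.75,5.37,4.98,9.19
escudier2017,tasquinimod,MKI,3.73,5.30,4.65,7.89
abou_alfa2016,codrituzumab,MKI,3.02,4.97,3.52,7.62
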