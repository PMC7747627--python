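genotype,trait,control,hnt,printed_pct_diff,exact
Everest,starch,59.80,46.87,-21.62,1
Jagger X060724,starch,59.27,48.17,-18.73,1
KS 070736K-1,starch,48.82,51.80,6.12,0
KS 070729K-26,starch,54.33,44.34,-18.40,0
KS 070717M-1,starch,56.07,37.20,-33.67,0
Larry,starch,49.27,45.31,-8.04,1
P1 X060725,starch,48.36,39.99,-17.32,0
SY-Monument,starch,63.23,59.40,-6.06,1
Tascosa,starch,67.77,51.15,-24.52,1
Tx86A5606,starch,59.66,51.02,-14.47,0
WB-4458,starch,63.49,59.98,-5.52,0
WB-Cedar,starch,78.29,64.66,-17.41,1
Everest,protein,14.92,15.69,5.22,0
Jagger X060724,protein,14.55,14.57,0.13,0
KS 070736K-1,protein,14.27,14.73,3.20,0
KS 070729K-26,protein,13.74,14.42,4.98,0
KS 070717M-1,protein,15.68,15.56,-0.73,0
Larry,protein,14.46,14.25,-1.45,1
P1 X060725,protein,14.36,14.99,4.37,0
SY-Monument,protein,13.13,14.02,6.80,0
Tascosa,protein,12.98,13.28,2.34,0
Tx86A5606,protein,12.64,13.21,4.51,1
WB-4458,protein,13.36,14.27,6.83,0
WB-Cedar,protein,14.95,14.92,-0.25,0
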