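comparison	fpkm_fold_change	qpcr_relative_expression
TIMP1 CGN/DRG	0.008111	0.013377
CASD1 CGN/DRG	1.546914	1.999634
RAB5B CGN/DRG	0.305764	0.442207
SLCO3A1 CGN/DRG	0.319529	0.088551
SNCG CGN/DRG	0.000423	0
APLP1 CGN/DRG	0.866076	0.866076
ATF3 CGN/DRG	0.048668	0.032352
ATF3 J1 CGN/ATF3 CGN	1.976821	0.146519
ATF3 J2 CGN/ATF3 CGN	1.239579	0.611443
ATF3 J3 CGN/ATF3 CGN	0.853864	0.844696
APLP1 CGN/ATP1A3 DRG	0.866076	0.860883
MATN2 J1 CGN/MATN2 CGN	0.846136	3.007829
PTEN J2 CGN/PTEN CGN	0.133626	0.139335
ATF3 J1 DRG/ATF3 DRG	0.227722	0.03412
ATF3 J2 DRG/ATF3 DRG	1.418459	0.098662
ATF3 J3 DRG/ATF3 DRG	0.1638	0.167082
PTEN J2 DRG/PTEN DRG	0.245028	0.002787
MATN2 J1 DRG/MATN2 DRG	2.453454	1.490104
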