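name,rsid,maf,r1_erneg,r2_erneg,r1_erpos,r2_erpos
10q26/FGFR2,rs2981582,0.38,1.08,1.18,1.28,1.74
16q12/TNRC9-TOX3,rs3803662,0.25,1.16,1.28,1.25,1.48
5q11/MAP3K1,rs889312,0.28,1.03,1.20,1.12,1.26
8q24/FAM84B-cMYC,rs13281615,0.40,0.99,1.09,1.11,1.29
11p15/LSP1,rs3817198,0.30,1.01,1.13,1.04,1.19
3p24/NEK10-SLC4A7,rs4973768,0.46,1.06,1.12,1.12,1.25
17q22/COX11,rs6504950,0.27,1.03,1.06,0.94,0.88
10p14/CASP8-D302H,rs1045485,0.13,0.95,0.82,0.89,0.83
2q35/TNP1-IGFBP5,rs13387042,0.52,1.05,1.18,1.08,1.29
1p11.2/NOTCH2-FCGR1B,rs1124933,0.40,1.03,1.07,1.22,1.42
14q24.1/RAD51L1,rs999737,0.24,1.01,0.76,0.93,0.69
5p12/MRPS30-FGFR10,rs10941679,0.26,1.03,1.01,1.17,1.18
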