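# Solidification survey: 18 common proteins, published per-protein P_HAP
# (percent of hexapeptide windows with steric-zipper energy <= -23 kcal/mol)
# and whether the protein solidified into an underwater glue.
index,protein,phap_percent,solidifies
1,Insulin,43.75,yes
2,Trypsin,32.94,yes
3,OVA,30.16,yes
4,Hemoglobin,25.00,yes
5,Lysozyme,23.39,yes
6,alpha-Lactalbumin,23.02,yes
7,HSA,20.26,yes
8,Chymotrypsin,19.62,yes
9,Transferrin,19.32,yes
10,beta-Lactoglobulin,18.42,yes
11,Myoglobin,18.40,yes
12,BSA,18.36,yes
13,Lactoferrin,17.14,yes
14,Thyroglobulin,16.77,yes
15,beta-Glucosidase,15.27,no
16,Amylase,13.96,no
17,Collagenase,13.79,no
18,beta-Galactosidase,12.66,no
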