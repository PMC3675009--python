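compound_id,n_true_hpcs,n_cross_family
ABT-869,345,249
AMG-706,274,202
AST-487,2415,1955
AZD-1152HQPA,506,374
BIRB-796,893,730
BMS-387032,728,447
CHIR-258,1577,800
CHIR-265,242,184
CI-1033,1247,704
CP-690550,11,5
CP-724714,115,89
Dasatinib,1848,1193
EKB-569,1133,684
Erlotinib,596,456
Flavopiridol,921,481
GW-2580,0,0
GW-786034,1443,809
Gefitinib,203,169
Imatinib,57,45
JNJ-7706621,4087,2761
LY-333531,634,314
Lapatinib,115,89
MLN-518,92,70
MLN-8054,435,301
PI-103,182,69
PKC-412,3419,2368
PTK-787,7,6
Roscovitine,593,335
SB-202190,644,513
SB-203580,738,546
SB-431542,133,69
SU-14813,4415,3116
Sorafenib,561,405
Staurosporine,17098,14802
Sunitinib,5525,4077
VX-680,2707,1786
VX-745,189,151
ZD-6474,1059,610
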