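protein_id	substrates	group	source_cluster
Sden_2708	chito-oligosaccharides; phytate; maltodextrin; maltose; chitin; xylan; xylose; pectin	I_DOM	3090
CPS_1021	chito-oligosaccharides; phytate; maltodextrin; maltose; chitin; xylan; xylose; pectin	I_DOM	3090
PSPTO_3242	chito-oligosaccharides; phytate; maltodextrin; maltose; chitin; xylan; xylose; pectin	I_DOM	3090
XCC2385	chito-oligosaccharides; phytate; maltodextrin; maltose; chitin; xylan; xylose; pectin	I_DOM	3090
MalA	maltodextrin; maltose	I_DOM	3090
XCC2469	chito-oligosaccharides; phytate; maltodextrin; maltose; chitin; xylan; xylose; pectin	I_DOM	3090
NagA	chitin; chito-oligosaccharides	I_DOM	3090
XCC2828	chito-oligosaccharides; phytate; maltodextrin; maltose; chitin; xylan; xylose; pectin	I_DOM	3090
SO_3514	chito-oligosaccharides; phytate; maltodextrin; maltose; chitin; xylan; xylose; pectin	I_DOM	3090
CC_0446	chito-oligosaccharides; phytate; maltodextrin; maltose; chitin; xylan; xylose; pectin	I_DOM	3090
XCC0120	chito-oligosaccharides; phytate; maltodextrin; maltose; chitin; xylan; xylose; pectin	I_DOM	3090
XCC2944	chito-oligosaccharides; phytate; maltodextrin; maltose; chitin; xylan; xylose; pectin	I_DOM	3090
XCC4120	chito-oligosaccharides; phytate; maltodextrin; maltose; chitin; xylan; xylose; pectin	I_DOM	3090
XCC2887	chito-oligosaccharides; phytate; maltodextrin; maltose; chitin; xylan; xylose; pectin	I_DOM	3090
RagA	digested proteins	I_DOM	720
SusC	starch/malto-oligo-saccharides	I_DOM	720
CsuF	chondroitin sulfate/hyaluronic acid	I_DOM	720
XCC4222	arabinose	I_DOM	427
SuxA	sucrose	I_DOM	952
Sfri_3988	sucrose	I_DOM	952
FecA	ferric-citrate	II_SiderophoreVitamin	3303
FmtA	ferric malleobactin	II_SiderophoreVitamin	410
PupA	pseudobactin	II_SiderophoreVitamin	410
FatA	anguibactin	II_SiderophoreVitamin	410
FcuA	ferrichrome	II_SiderophoreVitamin	410
ViuA	vibriobactin	II_SiderophoreVitamin	410
RhtA	rhizobactin 1021	II_SiderophoreVitamin	410
BfrI	ferrioxamine B	II_SiderophoreVitamin	410
Bcep18194_b2436	ferric ornibactin	II_SiderophoreVitamin	410
PupB	pseudobactin M114	II_SiderophoreVitamin	410
IutA	aerobactin	II_SiderophoreVitamin	410
SftP	hexylsulfate	II_SiderophoreVitamin	410
XCC0674	siderophores	II_SiderophoreVitamin	410
CPS_0067	siderophores	II_SiderophoreVitamin	410
FhuE	coprogen; rhodoturolic acid	II_SiderophoreVitamin	410
PbuA	pseudobactin M114	II_SiderophoreVitamin	410
FpvA	pyoverdine	II_SiderophoreVitamin	410
FauA	alcaligin	II_SiderophoreVitamin	410
FptA	pyochelin	II_SiderophoreVitamin	410
SO_2715	siderophores	II_SiderophoreVitamin	410
PhuR	siderophores	II_SiderophoreVitamin	410
PrhA	siderophores	II_SiderophoreVitamin	410
FctA	chrysobactin	II_SiderophoreVitamin	410
BfrZ	siderophores	II_SiderophoreVitamin	410
FyuA	yersiniabactin	II_SiderophoreVitamin	410
BauA	siderophores	II_SiderophoreVitamin	410
Fiu	catecholates	II_SiderophoreVitamin	410
FhuA	ferrichrome	II_SiderophoreVitamin	410
VciA	siderophores	II_SiderophoreVitamin	410
PiuA_Fiu	catecholates	II_SiderophoreVitamin	410
FoxA	desferrioxamine	II_SiderophoreVitamin	410
FegA	ferrichrome	II_SiderophoreVitamin	410
OptS	siderophores	II_SiderophoreVitamin	410
IrpC	siderophores	II_SiderophoreVitamin	410
OrbA	ferric ornibactin	II_SiderophoreVitamin	410
XCC3067	vitamin B12; catecholates; enterobactin; 2,3-dihydroxybenzoylserine	II_SiderophoreVitamin	973
PA1271	vitamin B12; catecholates	II_SiderophoreVitamin	973
RS02718	vitamin B12; catecholates	II_SiderophoreVitamin	973
VC0156	vitamin B12; catecholates	II_SiderophoreVitamin	973
BtuB	vitamin B12	II_SiderophoreVitamin	973
CC1750	vitamin B12; catecholates	II_SiderophoreVitamin	973
BPSL0976	vitamin B12; catecholates	II_SiderophoreVitamin	973
Saro0693	vitamin B12; catecholates	II_SiderophoreVitamin	973
CirA	catecholates; 2,3-dihydroxybenzoylserine	II_SiderophoreVitamin	973
FepA	enterobactin	II_SiderophoreVitamin	973
PirA	enterobactin	II_SiderophoreVitamin	973
PfeA	enterobactin	II_SiderophoreVitamin	973
IroN	enterobactin	II_SiderophoreVitamin	973
CfrA	enterobactin	II_SiderophoreVitamin	973
IrgA	enterobactin	II_SiderophoreVitamin	973
BfrA	enterobactin	II_SiderophoreVitamin	973
BfeA	enterobactin	II_SiderophoreVitamin	973
RSP_2402	vitamin B12; catecholates	II_SiderophoreVitamin	973
SO_0815	vitamin B12	II_SiderophoreVitamin	325
BF1991	fibronectin; thiamin	II_SiderophoreVitamin	180
BF0615	fibronectin; thiamin	II_SiderophoreVitamin	180
PG1899	fibronectin; thiamin	II_SiderophoreVitamin	180
GOX1347	thiamin	II_SiderophoreVitamin	2835
HumA	heme	III_Heme	1609
HxuC	heme	III_Heme	1856
PfhR	heme	III_Heme	1856
HgbA	heme	III_Heme	1856
HemR	heme	III_Heme	1856
HpuB	heme	III_Heme	1856
HasR	heme	III_Heme	1856
HmbR	heme	III_Heme	1856
HmuR	heme	III_Heme	1856
ChuA	heme	III_Heme	1856
ShuA	heme	III_Heme	1856
VctA	heme	III_Heme	1856
TbpA	heme	III_Heme	1856
FrpB4	heme	III_Heme	1856
HuvA	heme	III_Heme	1856
TdhA	heme	III_Heme	1856
BLL7076	heme	III_Heme	1856
LbpA	heme	III_Heme	1856
HutA	heme	III_Heme	1856
HutR	heme	III_Heme	1856
NosA	copper	IV_Metal	767
OprC	copper; copper chelate	IV_Metal	767
Bll6948	nickel; cobalt	IV_Metal	987
Daro_3944	nickel; cobalt	IV_Metal	987
RPA_4757	nickel; cobalt	IV_Metal	987
pHCG3_081	nickel; cobalt	IV_Metal	987
Daro_1684	nickel; cobalt	IV_Metal	987
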