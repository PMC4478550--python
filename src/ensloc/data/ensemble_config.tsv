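# ensLOC default ensemble: 60 binary classifier nodes.
# level 1 = quality control, level 2 = cell-cycle stage, level 3 = localization.
# Level-3 nodes form 20 subgroups = (group, variant) pairs. Within a subgroup,
# class membership is the conjunction (AND) of the primary node and all
# discriminator nodes; a class with several variants (cortical patches,
# cell periphery, spindle pole) is the disjunction (OR) over the variants
# applicable to the cell's cycle stage. "refinement" nodes emit
# sub-annotations and never veto membership.
# gate: which cells the node is evaluated on ("" = all QC-passing cells).
# n_pos/n_neg: positive/negative training-object counts of the original
# handpicked training sets (reference only; phantom training sets are
# generated at run time).
classifier_id	name	level	group	class	variant	role	gate	n_pos	n_neg
1.1.1	DEAD	1	QC	-	-	qc	-	960	1541
1.1.2	GHOST	1	QC	-	-	qc	-	1840	2398
2.1.1	UNBUDDED	2	Cycle	-	-	cycle	-	1095	1582
2.1.2	SMALLBUDDED	2	Cycle	-	-	cycle	-	434	733
2.1.3	LARGEMEDIUMBUDDED	2	Cycle	-	-	cycle	-	727	1508
3.1.1	CYTOPLASM	3	3.1 Cytoplasm	cytoplasm	-	primary	-	3493	4285
3.1.2	CYTOPLASMNOTNUCLEAR	3	3.1 Cytoplasm	cytoplasm	-	refinement	-	2075	1419
3.2.1	ENDOSOME	3	3.2 Endosome	endosome	-	primary	-	2245	4730
3.2.2	ENDOSOME_CYTOPLASM	3	3.2 Endosome	endosome	-	discriminator	-	2245	3493
3.2.3	ENDOSOME_NUCLEI	3	3.2 Endosome	endosome	-	discriminator	-	2245	5612
3.2.4	ENDOSOME_SPINDLEPOLE	3	3.2 Endosome	endosome	-	discriminator	-	2245	3397
3.2.5	ENDOSOME_MITOCHONDRIA	3	3.2 Endosome	endosome	-	discriminator	-	2245	6315
3.3.1	ER	3	3.3 ER	ER	-	primary	-	5274	4259
3.3.2	ER_CYTOPLASM	3	3.3 ER	ER	-	discriminator	-	5274	3493
3.3.3	ER_VACUOLEVACUOLARMEMBRANE	3	3.3 ER	ER	-	discriminator	-	5274	3893
3.3.4	ER_CELLPERIPHERY	3	3.3 ER	ER	-	discriminator	-	5274	4059
3.4.1	GOLGI	3	3.4 Golgi	Golgi	-	primary	-	1994	1838
3.4.2	GOLGI_MITOCHONDRIA	3	3.4 Golgi	Golgi	-	discriminator	-	1994	6315
3.4.3	GOLGI_ENDOSOME	3	3.4 Golgi	Golgi	-	discriminator	-	1994	2245
3.4.4	GOLGI_CYTOPLASM	3	3.4 Golgi	Golgi	-	discriminator	-	1994	3493
3.5.1	MITOCHONDRIA	3	3.5 Mitochondria	mitochondria	-	primary	-	6315	7894
3.6.1	NUCLEARPERIPHERY	3	3.6 Nuclear Periphery	nuclear periphery	-	primary	-	2668	4367
3.7.1	NUCLEI	3	3.7 Nucleus	nucleus	-	primary	-	5612	6881
3.7.2	NUCLEINOTCYTOPLASM	3	3.7 Nucleus	nucleus	-	refinement	-	1398	989
3.8.1	NUCLEOLUS	3	3.8 Nucleolus	nucleolus	-	primary	-	3882	5332
3.9.1	PEROXISOME	3	3.9 Peroxisome	peroxisome	-	primary	-	1256	2099
3.9.2	PEROXISOME_GOLGI	3	3.9 Peroxisome	peroxisome	-	discriminator	-	1256	1993
3.9.3	PEROXISOME_SPINDLEPOLE	3	3.9 Peroxisome	peroxisome	-	discriminator	-	1256	3397
3.9.4	PEROXISOME_MITOCHONDRIA	3	3.9 Peroxisome	peroxisome	-	discriminator	-	1256	6315
3.10.1	VACUOLEVACUOLARMEMBRANE-COMBINED	3	3.10 Vacuole/Vacuolar Membrane	vacuole/vacuolar membrane	-	primary	-	3893	3352
3.10.2	VACUOLE_VACUOLARMEMBRANE	3	3.10 Vacuole/Vacuolar Membrane	vacuole/vacuolar membrane	-	refinement	-	2224	1846
3.11.1	CORTICALPATCHESUNBUDDED	3	3.11 Cortical Patches	cortical patches	unbudded	primary	unbudded	1813	1279
3.11.2	CORTICALPATCHESUNBUDDED_CYTOPLASM	3	3.11 Cortical Patches	cortical patches	unbudded	discriminator	unbudded	1813	1661
3.11.3	CORTICALPATCHESUNBUDDED_MITOCHONDRIA	3	3.11 Cortical Patches	cortical patches	unbudded	discriminator	unbudded	1813	4440
3.11.4	CORTICALPATCHESBUDDED	3	3.11 Cortical Patches	cortical patches	budded	primary	budded	1345	2171
3.11.5	CORTICALPATCHESBUDDED_CELLPERIPHERY	3	3.11 Cortical Patches	cortical patches	budded	discriminator	budded	1345	1059
3.11.6	CORTICALPATCHESBUDDED_MITOCHONDRIA	3	3.11 Cortical Patches	cortical patches	budded	discriminator	budded	1345	1875
3.11.7	CORTICALPATCHESBUDDED_CYTOPLASM	3	3.11 Cortical Patches	cortical patches	budded	discriminator	budded	1345	1022
3.12.1	BUD	3	3.12 Bud	bud	-	primary	budded	1619	1691
3.13.1	BUDNECK	3	3.13 Budneck	budneck	-	primary	budded	2170	3095
3.13.2	BUDNECK_BUD	3	3.13 Budneck	budneck	-	discriminator	budded	2170	1619
3.13.3	BUDNECK_CELLPERIPHERY	3	3.13 Budneck	budneck	-	discriminator	budded	2170	1059
3.13.4	BUDNECK_MITOCHONDRIA	3	3.13 Budneck	budneck	-	discriminator	budded	2170	1875
3.13.5	BUDNECK_CYTOPLASM	3	3.13 Budneck	budneck	-	discriminator	budded	2170	1022
3.13.6	BUDNECK_NUCLEI	3	3.13 Budneck	budneck	-	discriminator	budded	2170	1313
3.14.1	BUDSITE	3	3.14 Budsite	budsite	-	primary	budded	453	637
3.14.2	BUDSITE_CYTOPLASM	3	3.14 Budsite	budsite	-	discriminator	budded	453	4955
3.14.3	BUDSITE_CELLPERIPHERY	3	3.14 Budsite	budsite	-	discriminator	budded	453	359
3.15.1	CELLPERIPHERYUNBUDDED	3	3.15 Cell Periphery	cell periphery	unbudded	primary	unbudded	2269	858
3.15.2	CELLPERIPHERYBUDDED	3	3.15 Cell Periphery	cell periphery	budded	primary	budded	1059	1688
3.16.1	SPINDLEPOLETWODOTFARBUDDED	3	3.16 Spindle Pole	spindle pole	twodotfar	primary	budded	416	966
3.16.2	SPINDLEPOLETWODOTFARBUDDED_BUDNECK	3	3.16 Spindle Pole	spindle pole	twodotfar	discriminator	budded	416	2170
3.16.3	SPINDLEPOLETWODOTFARBUDDED_NUCLEARPERIPHERY	3	3.16 Spindle Pole	spindle pole	twodotfar	discriminator	budded	416	492
3.16.4	SPINDLEPOLETWODOTFARBUDDED_NUCLEOLUS	3	3.16 Spindle Pole	spindle pole	twodotfar	discriminator	budded	416	1109
3.16.5	SPINDLEPOLETWODOTCLOSEBUDDED	3	3.16 Spindle Pole	spindle pole	twodotclose	primary	budded	306	1016
3.16.6	SPINDLEPOLETWODOTCLOSEBUDDED_BUDNECK	3	3.16 Spindle Pole	spindle pole	twodotclose	discriminator	budded	306	2170
3.16.7	SPINDLEPOLETWODOTCLOSEBUDDED_MITOCHONDRIA	3	3.16 Spindle Pole	spindle pole	twodotclose	discriminator	budded	306	1875
3.16.8	SPINDLEPOLETWODOTCLOSEBUDDED_NUCLEARPERIPHERY	3	3.16 Spindle Pole	spindle pole	twodotclose	discriminator	budded	306	492
3.16.9	SPINDLEPOLETWODOTCLOSEBUDDED_NUCLEOLUS	3	3.16 Spindle Pole	spindle pole	twodotclose	discriminator	budded	306	1109
3.16.10	SPINDLEPOLEONEDOT	3	3.16 Spindle Pole	spindle pole	onedot	primary	-	2675	3676
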