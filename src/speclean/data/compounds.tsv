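# Curated compound universe for the synthetic dirty-library generator
# and the offline name resolver. Masses computed from the formula with
# the package's element tables; structure fields are mutually
# consistent RDKit-canonical renderings.
# name	formula	smiles	inchi	inchikey	monoisotopic_mass	average_mass
nicotinic acid	C6H5NO2	O=C(O)c1cccnc1	InChI=1S/C6H5NO2/c8-6(9)5-2-1-3-7-4-5/h1-4H,(H,8,9)	PVNIIMVLHYAWGP-UHFFFAOYSA-N	123.032028	123.111000
adenine	C5H5N5	Nc1ncnc2nc[nH]c12	InChI=1S/C5H5N5/c6-4-3-5(9-1-7-3)10-2-8-4/h1-2H,(H3,6,7,8,9,10)	GFFGJBXGBJISGV-UHFFFAOYSA-N	135.054495	135.130000
pyridoxine	C8H11NO3	Cc1ncc(CO)c(CO)c1O	InChI=1S/C8H11NO3/c1-5-8(12)7(4-11)6(3-10)2-9-5/h2,10-12H,3-4H2,1H3	LXNHXLLTXMVWPM-UHFFFAOYSA-N	169.073893	169.180000
serotonin	C10H12N2O	NCCc1c[nH]c2ccc(O)cc12	InChI=1S/C10H12N2O/c11-4-3-7-6-12-10-2-1-8(13)5-9(7)10/h1-2,5-6,12-13H,3-4,11H2	QZAYGJVTTNCVMB-UHFFFAOYSA-N	176.094963	176.219000
glucose	C6H12O6	OCC1OC(O)C(O)C(O)C1O	InChI=1S/C6H12O6/c7-1-2-3(8)4(9)5(10)6(11)12-2/h2-11H,1H2	WQZGKKKJIJFFOK-UHFFFAOYSA-N	180.063388	180.156000
citric acid	C6H8O7	O=C(O)CC(O)(CC(=O)O)C(=O)O	InChI=1S/C6H8O7/c7-3(8)1-6(13,5(11)12)2-4(9)10/h13H,1-2H2,(H,7,8)(H,9,10)(H,11,12)	KRKNYBCHXYNGOX-UHFFFAOYSA-N	192.027003	192.123000
caffeine	C8H10N4O2	Cn1c(=O)c2c(ncn2C)n(C)c1=O	InChI=1S/C8H10N4O2/c1-10-4-9-6-5(10)7(13)12(3)8(14)11(6)2/h4H,1-3H3	RYYVLZVUVIJVGH-UHFFFAOYSA-N	194.080376	194.194000
tryptophan	C11H12N2O2	NC(Cc1c[nH]c2ccccc12)C(=O)O	InChI=1S/C11H12N2O2/c12-9(11(14)15)5-7-6-13-10-4-2-1-3-8(7)10/h1-4,6,9,13H,5,12H2,(H,14,15)	QIVBCDIJIAJPQS-UHFFFAOYSA-N	204.089878	204.229000
ibuprofen	C13H18O2	CC(C)Cc1ccc(C(C)C(=O)O)cc1	InChI=1S/C13H18O2/c1-9(2)8-11-4-6-12(7-5-11)10(3)13(14)15/h4-7,9-10H,8H2,1-3H3,(H,14,15)	HEFNNWSXXWATRW-UHFFFAOYSA-N	206.130680	206.285000
naproxen	C14H14O3	COc1ccc2ccc(C(C)C(=O)O)cc2c1	InChI=1S/C14H14O3/c1-9(14(15)16)11-4-3-10-5-6-13(17-2)8-12(10)7-11/h3-9H,1-2H3,(H,15,16)	MIJUDPHTZVRTNN-UHFFFAOYSA-N	230.094294	230.263000
melatonin	C13H16N2O2	COc1ccc2[nH]cc(CCNC(C)=O)c2c1	InChI=1S/C13H16N2O2/c1-9(16)14-6-5-10-8-15-13-4-3-11(17-2)7-12(10)13/h3-4,7-8,15H,5-6H2,1-2H3,(H,14,16)	DRLFMBDRBRZALE-UHFFFAOYSA-N	232.121178	232.283000
biotin	C10H16N2O3S	O=C(O)CCCCC1SCC2NC(=O)NC21	InChI=1S/C10H16N2O3S/c13-8(14)4-2-1-3-7-9-6(5-16-7)11-10(15)12-9/h6-7,9H,1-5H2,(H,13,14)(H2,11,12,15)	YBJHBAHKTGYVGT-UHFFFAOYSA-N	244.088163	244.316000
estradiol	C18H24O2	CC12CCC3c4ccc(O)cc4CCC3C1CCC2O	InChI=1S/C18H24O2/c1-18-9-8-14-13-5-3-12(19)10-11(13)2-4-15(14)16(18)6-7-17(18)20/h3,5,10,14-17,19-20H,2,4,6-9H2,1H3	VOXZDWNPVJITMN-UHFFFAOYSA-N	272.177630	272.388000
testosterone	C19H28O2	CC12CCC(=O)C=C1CCC1C2CCC2(C)C(O)CCC12	InChI=1S/C19H28O2/c1-18-9-7-13(20)11-12(18)3-4-14-15-5-6-17(21)19(15,2)10-8-16(14)18/h11,14-17,21H,3-10H2,1-2H3	MUMGGOZAMZWBJJ-UHFFFAOYSA-N	288.208930	288.431000
quercetin	C15H10O7	O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12	InChI=1S/C15H10O7/c16-7-4-10(19)12-11(5-7)22-15(14(21)13(12)20)6-1-2-8(17)9(18)3-6/h1-5,16-19,21H	REFJWTPEDVJJIY-UHFFFAOYSA-N	302.042653	302.238000
warfarin	C19H16O4	CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O	InChI=1S/C19H16O4/c1-12(20)11-15(13-7-3-2-4-8-13)17-18(21)14-9-5-6-10-16(14)23-19(17)22/h2-10,15,21H,11H2,1H3	PJVWKTKQMONHTI-UHFFFAOYSA-N	308.104859	308.333000
penicillin G	C16H18N2O4S	CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O	InChI=1S/C16H18N2O4S/c1-16(2)12(15(21)22)18-13(20)11(14(18)23-16)17-10(19)8-9-6-4-3-5-7-9/h3-7,11-12,14H,8H2,1-2H3,(H,17,19)(H,21,22)	JGSARLDLIJGVTE-UHFFFAOYSA-N	334.098728	334.397000
sucrose	C12H22O11	OCC1OC(OC2(CO)OC(CO)C(O)C2O)C(O)C(O)C1O	InChI=1S/C12H22O11/c13-1-4-6(16)8(18)9(19)11(21-4)23-12(3-15)10(20)7(17)5(2-14)22-12/h4-11,13-20H,1-3H2	CZMRCDWAGMRECN-UHFFFAOYSA-N	342.116211	342.297000
chlorogenic acid	C16H18O9	O=C(C=Cc1ccc(O)c(O)c1)OC1CC(O)(C(=O)O)CC(O)C1O	InChI=1S/C16H18O9/c17-9-3-1-8(5-10(9)18)2-4-13(20)25-12-7-16(24,15(22)23)6-11(19)14(12)21/h1-5,11-12,14,17-19,21,24H,6-7H2,(H,22,23)	CWVRJTMFETXNAD-UHFFFAOYSA-N	354.095082	354.311000
cortisol	C21H30O5	CC12CCC(=O)C=C1CCC1C2C(O)CC2(C)C1CCC2(O)C(=O)CO	InChI=1S/C21H30O5/c1-19-7-5-13(23)9-12(19)3-4-14-15-6-8-21(26,17(25)11-22)20(15,2)10-16(24)18(14)19/h9,14-16,18,22,24,26H,3-8,10-11H2,1-2H3	JYGXADMDTFJGBT-UHFFFAOYSA-N	362.209324	362.466000
riboflavin	C17H20N4O6	Cc1cc2nc3c(=O)[nH]c(=O)nc-3n(CC(O)C(O)C(O)CO)c2cc1C	InChI=1S/C17H20N4O6/c1-7-3-9-10(4-8(7)2)21(5-11(23)14(25)12(24)6-22)15-13(18-9)16(26)20-17(27)19-15/h3-4,11-12,14,22-25H,5-6H2,1-2H3,(H,20,26,27)	AUNGANRZJHBGPY-UHFFFAOYSA-N	376.138284	376.369000
cholesterol	C27H46O	CC(C)CCCC(C)C1CCC2C3CC=C4CC(O)CCC4(C)C3CCC12C	InChI=1S/C27H46O/c1-18(2)7-6-8-19(3)23-11-12-24-22-10-9-20-17-21(28)13-15-26(20,4)25(22)14-16-27(23,24)5/h9,18-19,21-25,28H,6-8,10-17H2,1-5H3	HVYWMOMLDIMFJA-UHFFFAOYSA-N	386.354866	386.664000
folic acid	C19H19N7O6	Nc1nc2ncc(CNc3ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc3)nc2c(=O)[nH]1	InChI=1S/C19H19N7O6/c20-19-25-15-14(17(30)26-19)23-11(8-22-15)7-21-10-3-1-9(2-4-10)16(29)24-12(18(31)32)5-6-13(27)28/h1-4,8,12,21H,5-7H2,(H,24,29)(H,27,28)(H,31,32)(H3,20,22,25,26,30)	OVBPIULPVIDEAO-UHFFFAOYSA-N	441.139681	441.404000
tetracycline	C22H24N2O8	CN(C)C1C(=O)C(C(N)=O)=C(O)C2(O)C(=O)C3=C(O)c4c(O)cccc4C(C)(O)C3CC12	InChI=1S/C22H24N2O8/c1-21(31)8-5-4-6-11(25)12(8)16(26)13-9(21)7-10-15(24(2)3)17(27)14(20(23)30)19(29)22(10,32)18(13)28/h4-6,9-10,15,25-26,29,31-32H,7H2,1-3H3,(H2,23,30)	NWXMGUDVXFXRIG-UHFFFAOYSA-N	444.153266	444.440000
verapamil	C27H38N2O4	COc1ccc(CCN(C)CCCC(C#N)(c2ccc(OC)c(OC)c2)C(C)C)cc1OC	InChI=1S/C27H38N2O4/c1-20(2)27(19-28,22-10-12-24(31-5)26(18-22)33-7)14-8-15-29(3)16-13-21-9-11-23(30-4)25(17-21)32-6/h9-12,17-18,20H,8,13-16H2,1-7H3	SGTNSNPWRIOYBX-UHFFFAOYSA-N	454.283158	454.611000
raffinose	C18H32O16	OCC1OC(OCC2OC(OC3(CO)OC(CO)C(O)C3O)C(O)C(O)C2O)C(O)C(O)C1O	InChI=1S/C18H32O16/c19-1-5-8(22)11(25)13(27)16(31-5)30-3-7-9(23)12(26)14(28)17(32-7)34-18(4-21)15(29)10(24)6(2-20)33-18/h5-17,19-29H,1-4H2	MUPFEKGTMRGPLJ-UHFFFAOYSA-N	504.169035	504.438000
ATP	C10H16N5O13P3	Nc1ncnc2c1ncn2C1OC(COP(=O)(O)OP(=O)(O)OP(=O)(O)O)C(O)C1O	InChI=1S/C10H16N5O13P3/c11-8-5-9(13-2-12-8)15(3-14-5)10-7(17)6(16)4(26-10)1-25-30(21,22)28-31(23,24)27-29(18,19)20/h2-4,6-7,10,16-17H,1H2,(H,21,22)(H,23,24)(H2,11,12,13)(H2,18,19,20)	ZKHQWZAMYRWXGA-UHFFFAOYSA-N	506.995745	507.182000
rutin	C27H30O16	CC1OC(OCC2OC(Oc3c(-c4ccc(O)c(O)c4)oc4cc(O)cc(O)c4c3=O)C(O)C(O)C2O)C(O)C(O)C1O	InChI=1S/C27H30O16/c1-8-17(32)20(35)22(37)26(40-8)39-7-15-18(33)21(36)23(38)27(42-15)43-25-19(34)16-13(31)5-10(28)6-14(16)41-24(25)9-2-3-11(29)12(30)4-9/h2-6,8,15,17-18,20-23,26-33,35-38H,7H2,1H3	IKGXIBQEEMLURG-UHFFFAOYSA-N	610.153385	610.521000
amiodarone	C25H29I2NO3	CCCCc1oc2ccccc2c1C(=O)c1cc(I)c(OCCN(CC)CC)c(I)c1	InChI=1S/C25H29I2NO3/c1-4-7-11-22-23(18-10-8-9-12-21(18)31-22)24(29)17-15-19(26)25(20(27)16-17)30-14-13-28(5-2)6-3/h8-10,12,15-16H,4-7,11,13-14H2,1-3H3	IYIKLHRQXLHMJQ-UHFFFAOYSA-N	645.023690	645.319000
erythromycin	C37H67NO13	CCC1OC(=O)C(C)C(OC2CC(C)(OC)C(O)C(C)O2)C(C)C(OC2OC(C)CC(N(C)C)C2O)C(C)(O)CC(C)C(=O)C(C)C(O)C1(C)O	InChI=1S/C37H67NO13/c1-14-25-37(10,45)30(41)20(4)27(39)18(2)16-35(8,44)32(51-34-28(40)24(38(11)12)15-19(3)47-34)21(5)29(22(6)33(43)49-25)50-26-17-36(9,46-13)31(42)23(7)48-26/h18-26,28-32,34,40-42,44-45H,14-17H2,1-13H3	ULGZDMOVFRHVEP-UHFFFAOYSA-N	733.461241	733.937000
digoxin	C41H64O14	CC1OC(OC2C(O)CC(OC3C(O)CC(OC4CCC5(C)C(CCC6C5CC(O)C5(C)C(C7=CC(=O)OC7)CCC65O)C4)OC3C)OC2C)CC(O)C1O	InChI=1S/C41H64O14/c1-19-36(47)28(42)15-34(50-19)54-38-21(3)52-35(17-30(38)44)55-37-20(2)51-33(16-29(37)43)53-24-8-10-39(4)23(13-24)6-7-26-27(39)14-31(45)40(5)25(9-11-41(26,40)48)22-12-32(46)49-18-22/h12,19-21,23-31,33-38,42-45,47-48H,6-11,13-18H2,1-5H3	LTMHDMANZUZIPE-UHFFFAOYSA-N	780.429607	780.949000
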