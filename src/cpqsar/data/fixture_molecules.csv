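id,name,casrn,smiles,class_label,expected_alerts,expected_group,nRNNOx,nPO4,N-067,N-078
ndma,N-nitrosodimethylamine,62-75-9,CN(C)N=O,2,SA_21,5,1,0,0,1
nmor,N-nitrosomorpholine,59-89-2,O1CCN(CC1)N=O,2,SA_21,5,1,0,0,1
chlordecone,Chlordecone (kepone),143-50-0,ClC1(Cl)C2(Cl)C3(Cl)C4(Cl)C1(Cl)C1(Cl)C4(Cl)C3(Cl)C1(Cl)C2=O,,SA_20,9,0,0,0,0
lindane,gamma-hexachlorocyclohexane,58-89-9,ClC1C(Cl)C(Cl)C(Cl)C(Cl)C1Cl,,SA_20,9,0,0,0,0
nitroaniline4,4-nitroaniline,100-01-6,Nc1ccc(cc1)[N+](=O)[O-],,SA_27;SA_28,7,0,0,0,0
dnph,2-4-dinitrophenylhydrazine,119-26-6,NNc1ccc(cc1[N+](=O)[O-])[N+](=O)[O-],,SA_13;SA_27,4,0,0,0,0
hexane,n-hexane,110-54-3,CCCCCC,1,,10,0,0,0,0
benzene,benzene,71-43-2,c1ccccc1,,,10,0,0,0,0
aniline,aniline,62-53-3,Nc1ccccc1,,SA_28,8,0,0,0,0
nitrobenzene,nitrobenzene,98-95-3,O=[N+]([O-])c1ccccc1,,SA_27,6,0,0,0,0
phenylhydrazine,phenylhydrazine,100-63-0,NNc1ccccc1,,SA_13,3,0,0,0,0
bromoethane,bromoethane,74-96-4,CCBr,,SA_8,2,0,0,0,0
ethylene_oxide,ethylene oxide,75-21-8,C1CO1,,SA_7,1,0,0,0,0
benzoquinone,p-benzoquinone,106-51-4,O=C1C=CC(=O)C=C1,,SA_12,9,0,0,0,0
nitrosobenzene,nitrosobenzene,586-96-9,O=Nc1ccccc1,,SA_25,9,0,0,0,1
diethylamine,diethylamine,109-89-7,CCNCC,,,10,0,0,1,0
trimethyl_phosphate,trimethyl phosphate,512-56-1,COP(=O)(OC)OC,,,10,0,1,0,0
parathion,parathion,56-38-2,S=P(OCC)(OCC)Oc1ccc(cc1)[N+](=O)[O-],,SA_27,6,0,1,0,0
dimethylnitramine,N-nitrodimethylamine,4164-28-7,CN(C)[N+](=O)[O-],,SA_23,9,0,0,0,0
azobenzene,azobenzene,103-33-3,c1ccc(cc1)N=Nc1ccccc1,,SA_29,9,0,0,0,2
mms,methyl methanesulfonate,66-27-3,COS(C)(=O)=O,,SA_2,9,0,0,0,0
anthracene,anthracene,120-12-7,c1ccc2cc3ccccc3cc2c1,,SA_18,9,0,0,0,0
carbazole,carbazole,86-74-8,c1ccc2c(c1)[nH]c1ccccc12,,SA_19,9,0,0,0,0
mechlorethamine,mechlorethamine,51-75-2,ClCCN(C)CCCl,,SA_5;SA_8,2,0,0,0,0
coumarin,coumarin,91-64-5,O=c1ccc2ccccc2o1,,SA_30,9,0,0,0,0
tcdd,2-3-7-8-tetrachlorodibenzodioxin,1746-01-6,Clc1cc2Oc3cc(Cl)c(Cl)cc3Oc2cc1Cl,,SA_31c,9,0,0,0,0
chloronaphthalene1,1-chloronaphthalene,90-13-1,Clc1cccc2ccccc12,,SA_31b,9,0,0,0,0
chlorobenzene,chlorobenzene,108-90-7,Clc1ccccc1,,SA_31a,9,0,0,0,0
thiourea,thiourea,62-56-6,NC(N)=S,,SA_17,9,0,0,0,0
acetanilide,acetanilide,103-84-4,CC(=O)Nc1ccccc1,,SA_28ter,9,0,0,0,0
nmethylaniline,N-methylaniline,100-61-8,CNc1ccccc1,,SA_28bis,9,0,0,0,0
pyridine_noxide,pyridine N-oxide,694-59-7,[O-][n+]1ccccc1,,SA_26,9,0,0,0,0
dmpt,3-3-dimethyl-1-phenyltriazene,7227-91-0,CN(C)N=Nc1ccccc1,,SA_22,9,0,0,0,2
vinyl_chloride,vinyl chloride,75-01-4,C=CCl,,SA_4,9,0,0,0,0
methyl_isocyanate,methyl isocyanate,624-83-9,CN=C=O,,SA_15,9,0,0,0,0
urethane,ethyl carbamate,51-79-6,CCOC(N)=O,,SA_16,9,0,0,0,0
acetaldehyde,acetaldehyde,75-07-0,CC=O,,SA_11,9,0,0,0,0
mvk,methyl vinyl ketone,78-94-4,C=CC(C)=O,,SA_10,9,0,0,0,0
acrolein,acrolein,107-02-8,C=CC=O,,SA_10;SA_11,9,0,0,0,0
ethyl_nitrite,ethyl nitrite,109-95-5,CCON=O,,SA_9,9,0,0,0,1
methylolacetamide,N-methylolacetamide,625-51-4,OCNC(C)=O,,SA_3,9,0,0,0,0
azomethane,azomethane,503-28-6,CN=NC,,SA_14,9,0,0,0,0
ethyl_vinyl_ether,ethyl vinyl ether,109-92-2,C=COCC,,SA_24,9,0,0,0,0
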