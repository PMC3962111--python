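# Benigni-Bossa structural alerts for carcinogenicity (Toxtree rulebase),
# authored as SMARTS from the published alert definitions.  Each record
# carries the mechanism tag (genotoxic / nongenotoxic) and one example
# molecule that must match the alert (exercised by the test suite).
version: "bb-carc-1.0"
alerts:
  - id: SA_2
    name: "alkyl (C<5) or benzyl ester of sulphonic or phosphonic acid"
    mechanism: genotoxic
    patterns:
      - "[$([CX4H3]),$([CX4H2][CX4H3]),$([CX4H2]c)][OX2][SX4](=[OX1])(=[OX1])[#6]"
      - "[$([CX4H3]),$([CX4H2][CX4H3]),$([CX4H2]c)][OX2][PX4](=[OX1])[#6]"
    example: "COS(C)(=O)=O"
  - id: SA_3
    name: "N-methylol derivatives"
    mechanism: genotoxic
    patterns:
      - "[NX3][CX4H2][OX2H]"
    example: "OCNC(C)=O"
  - id: SA_4
    name: "monohaloalkene"
    mechanism: genotoxic
    patterns:
      - "[CX3]=[CX3]([F,Cl,Br,I])"
    example: "C=CCl"
  - id: SA_5
    name: "S or N mustard"
    mechanism: genotoxic
    patterns:
      - "[F,Cl,Br,I][CX4H2][CX4H2][NX3,SX2][CX4H2][CX4H2][F,Cl,Br,I]"
    example: "ClCCN(C)CCCl"
  - id: SA_7
    name: "epoxides and aziridines"
    mechanism: genotoxic
    patterns:
      - "[CX4]1[OX2][CX4]1"
      - "[CX4]1[NX3][CX4]1"
    example: "C1CO1"
  - id: SA_8
    name: "aliphatic halogens"
    mechanism: genotoxic
    patterns:
      - "[CX4;!$([C;R]([C;R][F,Cl,Br,I]))][Cl,Br,I]"
    example: "CCBr"
  - id: SA_9
    name: "alkyl nitrite"
    mechanism: genotoxic
    patterns:
      - "[CX4][OX2][NX2]=[OX1]"
    example: "CCON=O"
  - id: SA_10
    name: "alpha,beta-unsaturated carbonyl"
    mechanism: genotoxic
    patterns:
      - "[CX3]=[CX3][CX3;!$([#6]1(=[OX1])[#6]=[#6][#6](=[OX1])[#6]=[#6]1);!$([#6]1(=[OX1])[#6](=[OX1])[#6]=[#6][#6]=[#6]1)]=[OX1]"
    example: "C=CC(C)=O"
  - id: SA_11
    name: "simple aldehyde"
    mechanism: genotoxic
    patterns:
      - "[CX3H1](=[OX1])[#6]"
    example: "CC=O"
  - id: SA_12
    name: "quinones"
    mechanism: genotoxic
    patterns:
      - "[OX1]=[#6]1[#6]=[#6][#6](=[OX1])[#6]=[#6]1"
      - "[OX1]=[#6]1[#6](=[OX1])[#6]=[#6][#6]=[#6]1"
      - "[OX1]=[CX3]1[CX3]=[CX3][CX3](=[OX1])c2ccccc21"
      - "[OX1]=[CX3]1c2ccccc2[CX3](=[OX1])c2ccccc21"
    example: "O=C1C=CC(=O)C=C1"
  - id: SA_13
    name: "hydrazine"
    mechanism: genotoxic
    patterns:
      - "[NX3+0;!$([N]=[OX1])][NX3+0;!$([N]=[OX1])]"
    example: "NNc1ccccc1"
  - id: SA_14
    name: "aliphatic azo and azoxy"
    mechanism: genotoxic
    patterns:
      - "[CX4][NX2]=[NX2][CX4]"
      - "[CX4][NX2]=[NX3+]([OX1-])[CX4]"
      - "[CX4][NX2]=[NX3](=[OX1])[CX4]"
    example: "CN=NC"
  - id: SA_15
    name: "isocyanate and isothiocyanate groups"
    mechanism: genotoxic
    patterns:
      - "[NX2]=[CX2]=[OX1]"
      - "[NX2]=[CX2]=[SX1]"
    example: "CN=C=O"
  - id: SA_16
    name: "alkyl carbamate and thiocarbamate"
    mechanism: genotoxic
    patterns:
      - "[NX3][CX3](=[OX1])[OX2][CX4]"
      - "[NX3][CX3](=[SX1])[OX2,SX2][CX4]"
    example: "CCOC(N)=O"
  - id: SA_17
    name: "thiocarbonyl"
    mechanism: nongenotoxic
    patterns:
      - "[CX3]=[SX1]"
    example: "NC(N)=S"
  - id: SA_18
    name: "polycyclic aromatic hydrocarbons"
    mechanism: genotoxic
    patterns:
      - "c1ccc2cc3ccccc3cc2c1"
      - "c1ccc2ccc3ccccc3c2c1"
      - "c1cc2ccc3cccc4ccc(c1)c2c34"
    example: "c1ccc2cc3ccccc3cc2c1"
  - id: SA_19
    name: "heterocyclic polycyclic aromatic hydrocarbons"
    mechanism: genotoxic
    patterns:
      - "c1ccc2nc3ccccc3cc2c1"
      - "c1ccc2c(c1)[nH]c1ccccc12"
      - "c1ccc2nc3ccccc3nc2c1"
    example: "c1ccc2c(c1)[nH]c1ccccc12"
  - id: SA_20
    name: "(poly)halogenated cycloalkanes"
    mechanism: nongenotoxic
    patterns:
      - "[C;R]([F,Cl,Br,I])[C;R]([F,Cl,Br,I])"
    example: "ClC1(Cl)C2(Cl)C3(Cl)C4(Cl)C1(Cl)C1(Cl)C4(Cl)C3(Cl)C1(Cl)C2=O"
  - id: SA_21
    name: "alkyl and aryl N-nitroso groups"
    mechanism: genotoxic
    patterns:
      - "[NX3][NX2]=[OX1]"
    example: "CN(C)N=O"
  - id: SA_22
    name: "azide and triazene groups"
    mechanism: genotoxic
    patterns:
      - "[NX2]=[NX2+]=[NX1-]"
      - "[NX1]=[NX2+]=[NX2-]"
      - "[NX3][NX2]=[NX2]"
    example: "CN(C)N=Nc1ccccc1"
  - id: SA_23
    name: "aliphatic N-nitro group"
    mechanism: genotoxic
    patterns:
      - "[NX3][$([NX3+](=[OX1])[OX1-]),$([NX3](=[OX1])=[OX1])]"
    example: "CN(C)[N+](=O)[O-]"
  - id: SA_24
    name: "alpha,beta-unsaturated aliphatic alkoxy group"
    mechanism: genotoxic
    patterns:
      - "[CX3]=[CX3][OX2][CX4]"
    example: "C=COCC"
  - id: SA_25
    name: "aromatic nitroso group"
    mechanism: genotoxic
    patterns:
      - "a[NX2]=[OX1]"
    example: "O=Nc1ccccc1"
  - id: SA_26
    name: "aromatic ring N-oxide"
    mechanism: genotoxic
    patterns:
      - "[nX3+][OX1-]"
    example: "[O-][n+]1ccccc1"
  - id: SA_27
    name: "nitro-aromatic"
    mechanism: genotoxic
    patterns:
      - "a[$([NX3+](=[OX1])[OX1-]),$([NX3](=[OX1])=[OX1])]"
    example: "O=[N+]([O-])c1ccccc1"
  - id: SA_28
    name: "primary aromatic amine, hydroxyl amine and its derived esters"
    mechanism: genotoxic
    patterns:
      - "[NX3H2]a"
      - "a[NX3H1][OX2H]"
      - "a[NX3][OX2][CX3]=[OX1]"
    example: "Nc1ccccc1"
  - id: SA_28bis
    name: "aromatic mono- and dialkylamine"
    mechanism: genotoxic
    patterns:
      - "a[NX3H1][CX4]"
      - "a[NX3]([CX4])[CX4]"
    example: "CNc1ccccc1"
  - id: SA_28ter
    name: "aromatic N-acyl amine"
    mechanism: genotoxic
    patterns:
      - "a[NX3][CX3]=[OX1]"
    example: "CC(=O)Nc1ccccc1"
  - id: SA_29
    name: "aromatic diazo"
    mechanism: genotoxic
    patterns:
      - "a[NX2]=[NX2]a"
    example: "c1ccc(cc1)N=Nc1ccccc1"
  - id: SA_30
    name: "coumarins and furocoumarins"
    mechanism: genotoxic
    patterns:
      - "[OX1]=[#6]1[#6]=[#6]c2ccccc2[OX2]1"
      - "O=c1ccc2ccccc2o1"
    example: "O=c1ccc2ccccc2o1"
  - id: SA_31a
    name: "halogenated benzene"
    mechanism: nongenotoxic
    patterns:
      - "[F,Cl,Br,I][cR1]1[cR1][cR1][cR1][cR1][cR1]1"
    example: "Clc1ccccc1"
  - id: SA_31b
    name: "halogenated polycyclic aromatic hydrocarbons"
    mechanism: nongenotoxic
    patterns:
      - "[F,Cl,Br,I]c1ccc2ccccc2c1"
      - "[F,Cl,Br,I]c1cccc2ccccc12"
    example: "Clc1cccc2ccccc12"
  - id: SA_31c
    name: "halogenated dibenzodioxins"
    mechanism: nongenotoxic
    patterns:
      - "[F,Cl,Br,I]c1ccc2Oc3ccccc3Oc2c1"
      - "[F,Cl,Br,I]c1ccc2Oc3ccccc3Sc2c1"
    example: "Clc1cc2Oc3cc(Cl)c(Cl)cc3Oc2cc1Cl"
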