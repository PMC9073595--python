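id,smiles,arylidene_class,carboxamide_class,printed_formula,printed_mw,required_pct_C,required_pct_H,required_pct_N,name
24,O=C(Nc3ccccc3)N1C/C(=C\c2ccccc2)C(=O)/C(=C/c2ccccc2)C1,phenyl,phenyl,C26H22N2O2,394.47,79.17,5.62,7.10,"3,5-Di[(E)-benzylidene]-4-oxo-N-phenylpiperidine-1-carboxamide"
25,O=C(Nc3ccc(Cl)cc3)N1C/C(=C\c2ccccc2)C(=O)/C(=C/c2ccccc2)C1,phenyl,4-Cl-phenyl,C26H21ClN2O2,428.92,72.81,4.94,6.53,"3,5-Di[(E)-benzylidene]-N-(4-chlorophenyl)-4-oxopiperidine-1-carboxamide"
26,O=C(Nc3ccc(OC)cc3)N1C/C(=C\c2ccccc2)C(=O)/C(=C/c2ccccc2)C1,phenyl,4-MeO-phenyl,C27H24N2O3,424.50,76.40,5.70,6.60,"3,5-Di[(E)-benzylidene]-N-(4-methoxyphenyl)-4-oxopiperidine-1-carboxamide"
27,O=C(NCC)N1C/C(=C\c2ccccc2)C(=O)/C(=C/c2ccccc2)C1,phenyl,ethyl,C22H22N2O2,346.43,76.28,6.40,8.09,"3,5-Di[(E)-benzylidene]-N-ethyl-4-oxopiperidine-1-carboxamide"
28,O=C(NCc3ccccc3)N1C/C(=C\c2ccccc2)C(=O)/C(=C/c2ccccc2)C1,phenyl,benzyl,C27H24N2O2,408.50,79.39,5.92,6.86,"N-Benzyl-3,5-di[(E)-benzylidene]-4-oxopiperidine-1-carboxamide"
29,O=C(Nc3ccccc3)N1C/C(=C\c2ccc(Cl)cc2)C(=O)/C(=C/c2ccc(Cl)cc2)C1,4-Cl-phenyl,phenyl,C26H20Cl2N2O2,463.36,67.40,4.35,6.05,"3,5-Bis[(E)-4-chlorobenzylidene]-4-oxo-N-phenylpiperidine-1-carboxamide"
30,O=C(Nc3ccc(Cl)cc3)N1C/C(=C\c2ccc(Cl)cc2)C(=O)/C(=C/c2ccc(Cl)cc2)C1,4-Cl-phenyl,4-Cl-phenyl,C26H19Cl3N2O2,497.80,62.73,3.85,5.63,"3,5-Bis[(E)-4-chlorobenzylidene]-N-(4-chlorophenyl)-4-oxopiperidine-1-carboxamide"
31,O=C(Nc3ccc(OC)cc3)N1C/C(=C\c2ccc(Cl)cc2)C(=O)/C(=C/c2ccc(Cl)cc2)C1,4-Cl-phenyl,4-MeO-phenyl,C27H22Cl2N2O3,493.38,65.73,4.49,5.68,"3,5-Bis[(E)-4-chlorobenzylidene]-N-(4-methoxyphenyl)-4-oxopiperidine-1-carboxamide"
32,O=C(NCC)N1C/C(=C\c2ccc(Cl)cc2)C(=O)/C(=C/c2ccc(Cl)cc2)C1,4-Cl-phenyl,ethyl,C22H20Cl2N2O2,415.31,63.62,4.85,6.75,"3,5-Bis[(E)-4-chlorobenzylidene]-N-ethyl-4-oxopiperidine-1-carboxamide"
33,O=C(NCc3ccccc3)N1C/C(=C\c2ccc(Cl)cc2)C(=O)/C(=C/c2ccc(Cl)cc2)C1,4-Cl-phenyl,benzyl,C27H22Cl2N2O2,477.39,67.93,4.65,5.87,"N-Benzyl-3,5-bis[(E)-4-chlorobenzylidene]-4-oxopiperidine-1-carboxamide"
34,O=C(Nc3ccccc3)N1C/C(=C\c2ccc(F)cc2)C(=O)/C(=C/c2ccc(F)cc2)C1,4-F-phenyl,phenyl,C26H20F2N2O2,430.45,72.55,4.68,6.51,"3,5-Bis[(E)-4-fluorobenzylidene]-4-oxo-N-phenylpiperidine-1-carboxamide"
35,O=C(Nc3ccc(Cl)cc3)N1C/C(=C\c2ccc(F)cc2)C(=O)/C(=C/c2ccc(F)cc2)C1,4-F-phenyl,4-Cl-phenyl,C26H19ClF2N2O2,464.90,67.17,4.12,6.03,"N-(4-Chlorophenyl)-3,5-bis[(E)-4-fluorobenzylidene]-4-oxopiperidine-1-carboxamide"
36,O=C(Nc3ccc(OC)cc3)N1C/C(=C\c2ccc(F)cc2)C(=O)/C(=C/c2ccc(F)cc2)C1,4-F-phenyl,4-MeO-phenyl,C27H22F2N2O3,460.48,70.43,4.82,6.08,"3,5-Bis[(E)-4-fluorobenzylidene]-N-(4-methoxyphenyl)-4-oxopiperidine-1-carboxamide"
37,O=C(NCC)N1C/C(=C\c2ccc(F)cc2)C(=O)/C(=C/c2ccc(F)cc2)C1,4-F-phenyl,ethyl,C22H20F2N2O2,382.41,69.10,5.27,7.33,"N-Ethyl-3,5-bis[(E)-4-fluorobenzylidene]-4-oxopiperidine-1-carboxamide"
38,O=C(NCc3ccccc3)N1C/C(=C\c2ccc(F)cc2)C(=O)/C(=C/c2ccc(F)cc2)C1,4-F-phenyl,benzyl,C27H22F2N2O2,444.48,72.96,4.99,6.30,"N-Benzyl-3,5-bis[(E)-4-fluorobenzylidene]-4-oxopiperidine-1-carboxamide"
39,O=C(Nc3ccccc3)N1C/C(=C\c2ccc(C)cc2)C(=O)/C(=C/c2ccc(C)cc2)C1,4-Me-phenyl,phenyl,C28H26N2O2,422.53,79.59,6.20,6.63,"3,5-Bis[(E)-4-methylbenzylidene]-4-oxo-N-phenylpiperidine-1-carboxamide"
40,O=C(Nc3ccc(OC)cc3)N1C/C(=C\c2ccc(C)cc2)C(=O)/C(=C/c2ccc(C)cc2)C1,4-Me-phenyl,4-MeO-phenyl,C29H28N2O3,452.55,76.97,6.24,6.19,"N-(4-Methoxyphenyl)-3,5-bis[(E)-4-methylbenzylidene]-4-oxopiperidine-1-carboxamide"
41,O=C(NCC)N1C/C(=C\c2ccc(C)cc2)C(=O)/C(=C/c2ccc(C)cc2)C1,4-Me-phenyl,ethyl,C24H26N2O2,374.48,76.98,7.00,7.48,"N-Ethyl-3,5-bis[(E)-4-methylbenzylidene]-4-oxopiperidine-1-carboxamide"
42,O=C(NCc3ccccc3)N1C/C(=C\c2ccc(C)cc2)C(=O)/C(=C/c2ccc(C)cc2)C1,4-Me-phenyl,benzyl,C29H28N2O2,436.56,79.79,6.47,6.42,"N-Benzyl-3,5-bis[(E)-4-methylbenzylidene]-4-oxopiperidine-1-carboxamide"
43,O=C(Nc3ccccc3)N1C/C(=C\c2ccc(OC)cc2)C(=O)/C(=C/c2ccc(OC)cc2)C1,4-MeO-phenyl,phenyl,C28H26N2O4,454.53,73.99,5.77,6.16,"3,5-Bis[(E)-4-methoxybenzylidene]-4-oxo-N-phenylpiperidine-1-carboxamide"
44,O=C(Nc3ccc(Cl)cc3)N1C/C(=C\c2ccc(OC)cc2)C(=O)/C(=C/c2ccc(OC)cc2)C1,4-MeO-phenyl,4-Cl-phenyl,C28H25ClN2O4,488.97,68.78,5.15,5.73,"N-(4-Chlorophenyl)-3,5-bis[(E)-4-methoxybenzylidene]-4-oxopiperidine-1-carboxamide"
45,O=C(Nc3ccc(OC)cc3)N1C/C(=C\c2ccc(OC)cc2)C(=O)/C(=C/c2ccc(OC)cc2)C1,4-MeO-phenyl,4-MeO-phenyl,C29H28N2O5,484.55,71.88,5.82,5.78,"3,5-Bis[(E)-4-methoxybenzylidene]-N-(4-methoxyphenyl)-4-oxopiperidine-1-carboxamide"
46,O=C(NCC)N1C/C(=C\c2ccc(OC)cc2)C(=O)/C(=C/c2ccc(OC)cc2)C1,4-MeO-phenyl,ethyl,C24H26N2O4,406.48,70.92,6.45,6.89,"N-Ethyl-3,5-bis[(E)-4-methoxybenzylidene]-4-oxopiperidine-1-carboxamide"
47,O=C(NCc3ccccc3)N1C/C(=C\c2ccc(OC)cc2)C(=O)/C(=C/c2ccc(OC)cc2)C1,4-MeO-phenyl,benzyl,C29H28N2O4,468.55,74.34,6.02,5.98,"N-Benzyl-3,5-bis[(E)-4-methoxybenzylidene]-4-oxopiperidine-1-carboxamide"
48,O=C(Nc3ccccc3)N1C/C(=C\c2cccs2)C(=O)/C(=C/c2cccs2)C1,2-thienyl,phenyl,C22H18N2O2S2,406.52,65.00,4.46,6.89,"(3E,5E)-4-Oxo-N-phenyl-3,5-bis(thiophen-2-ylmethylene)piperidine-1-carboxamide"
49,O=C(Nc3ccc(OC)cc3)N1C/C(=C\c2cccs2)C(=O)/C(=C/c2cccs2)C1,2-thienyl,4-MeO-phenyl,C23H20N2O3S2,436.54,63.28,4.62,6.42,"(3E,5E)-N-(4-Methoxyphenyl)-4-oxo-3,5-bis(thiophen-2-ylmethylene)piperidine-1-carboxamide"
50,O=C(NCC)N1C/C(=C\c2cccs2)C(=O)/C(=C/c2cccs2)C1,2-thienyl,ethyl,C18H18N2O2S2,358.47,60.31,5.06,7.81,"(3E,5E)-N-Ethyl-4-oxo-3,5-bis(thiophen-2-ylmethylene)piperidine-1-carboxamide"
51,O=C(NCc3ccccc3)N1C/C(=C\c2cccs2)C(=O)/C(=C/c2cccs2)C1,2-thienyl,benzyl,C23H20N2O2S2,420.55,65.69,4.79,6.66,"(3E,5E)-N-Benzyl-4-oxo-3,5-bis(thiophen-2-ylmethylene)piperidine-1-carboxamide"
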