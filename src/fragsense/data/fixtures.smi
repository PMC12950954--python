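# fragsense fixture structures v1
# SMILES<TAB>name
CNCc1ccc(-c2cccnc2)s1	bd_b10
C[n+]1cccc(C(=O)[O-])c1	trigonelline
O=C1/C(=C\c2ccncc2)CCC/C1=C\c1ccncc1	sc66
C=CCc1ccc(O)c(-c2cc(CC=C)ccc2O)c1	honokiol
COc1ccc(CCC(=O)c2ccc(O)cc2)c(OC)c1	loureirin_a
[Se]=C=NCCCCc1ccccc1	isc_4
NCCc1c[nH]c2ccccc12	tryptamine
CNCCc1c[nH]c2ccc(O)cc12	n_methylserotonin
[NH3+]CCc1c[nH]c2ccc(O)cc12	serotonin_1plus
CNC[C@H](O)c1ccc(O)c(OC)c1	metanephrine
O=CCc1c[nH]c2ccccc12	indol_3_ylacetaldehyde
NC1=NC(=O)N(C=C1)[C@@H]1O[C@H](CO)[C@@H](O)C1(F)F	gemcitabine
CNCCCN1c2ccccc2CCc2ccccc21	desipramine
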