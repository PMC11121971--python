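label,units,linkage,smiles_printed,biodegradation_pct
AA-BDO-AA-BDO,AA;BDO;AA;BDO,ester,C(CCCO)OC(=O)CCCCC(=O)OCCCCOC(=O)CCCCC(=O)O,50.23
AA-DAF-AA-DAF,AA;DAF;AA;DAF,amide,NCc1ccc(o1)CNC(=O)CCCCC(=O)NCc1ccc(o1)CNC(=O)CCCCC(=O)N,1.59
AA-GLY-AA-GLY,AA;GLY;AA;GLY,ester,C(C(O)CO)OC(=O)CCCCC(=O)OCC(O)COC(=O)CCCCC(=O)O,46.9
AA-GLY-AA-ERY,AA;GLY;AA;ERY,ester,OCC(O)C(O)COC(=O)CCCCC(=O)OCC(O)COC(=O)CCCCC(=O)O,30.9
BDO-FDCA-BDO-AA,AA;BDO;FDCA;BDO,ester,O=C(CCCCC(=O)O)OCCCCOC(=O)c1ccc(o1)C(=O)OCCCCO,26.81
BDO-FDCA-BDO-FDCA,FDCA;BDO;FDCA;BDO,ester,OCCCCOC(=O)c1ccc(o1)C(=O)OCCCCOC(=O)c1ccc(o1)C(=O)O,15.22
BDO-TA-BDO-TA,TA;BDO;TA;BDO,ester,OCCCCOC(=O)c1ccc(cc1)C(=O)OCCCCOC(=O)c1ccc(cc1)C(=O)O,37.92
FDCA-GLY-AA-GLY,FDCA;GLY;AA;GLY,ester,OC(COC(=O)c1ccc(o1)C(=O)O)COC(=O)CCCCC(=O)OCC(O)CO,22.55
FDCA-GLY-FDCA-GLY,FDCA;GLY;FDCA;GLY,ester,OCC(O)COC(=O)c1ccc(o1)C(=O)OCC(O)COC(=O)c1ccc(o1)C(=O)O,18.36
GLY-TA-GLY-TA,TA;GLY;TA;GLY,ester,OCC(COC(=O)c1ccc(cc1)C(=O)OCC(COC(=O)c1ccc(cc1)C(=O)O)O)O,50.12
TA-BDO-AA-BDO,AA;BDO;TA;BDO,ester,O=C(CCCCC(=O)O)OCCCCOC(=O)c1ccc(cc1)C(=O)OCCCCO,37.48
TA-GLY-AA-GLY,TA;GLY;AA;GLY,ester,OC(COC(=O)c1ccc(cc1)C(=O)O)COC(=O)CCCCC(=O)OCC(O)CO,19.38
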