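sample,group,inoculum,thod,bod5,bod10,bod21,dt5,dt10,dt21
FDCA,monomer,Trieste,4.34,5.05,12.90,23.50,1.16,2.82,6.83
FDCA,monomer,Zaule,4.34,16.35,46.15,53.65,3.77,10.63,12.59
TA,monomer,Trieste,7.60,0.00,1.25,2.15,0.00,0.08,0.08
TA,monomer,Zaule,7.60,54.25,98.15,102.6,7.14,12.91,13.50
AA,monomer,Trieste,6.38,65.77,128.36,200.65,10.31,20.12,31.8
AA,monomer,Zaule,6.38,89.00,101.85,110.15,13.95,15.96,17.26
BDO,monomer,Trieste,13.62,30.10,69.50,128.90,2.21,5.10,9.43
BDO,monomer,Zaule,13.62,45.65,82.05,96.10,3.35,6.02,7.06
GLY,monomer,Trieste,5.30,15.50,32.80,55.95,2.92,6.18,10.51
GLY,monomer,Zaule,5.30,55.80,76.95,102.45,10.53,14.52,19.33
ERY,monomer,Trieste,3.98,11.95,24.65,44.85,2.99,6.55,14.22
DMT,monomer,Trieste,7.69,1.10,18.60,48.30,0.14,2.28,6.15
DMF,monomer,Trieste,5.48,11.9,18.35,24.25,2.17,3.23,5.28
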