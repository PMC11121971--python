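sample,group,inoculum,thod,bod5,bod10,bod21,dt5,dt10,dt21
BDO-FDCA,co,Trieste,2.24,9.45,21.20,34.10,4.22,9.46,15.22
BDO-TA,co,Trieste,2.19,35.40,65.80,83.05,16.16,30.05,37.92
BDO-AA,co,Trieste,1.32,25.95,45.40,66.30,19.66,34.20,49.95
GLY-FDCA,co,Trieste,1.59,14.05,18.90,29.20,8.84,11.89,18.36
GLY-TA,co,Trieste,1.30,27.30,40.45,65.15,21.00,34.39,50.23
GLY-AA,co,Trieste,1.05,11.70,24.85,49.25,11.14,23.67,46.90
BDO FDCA AA,ter,Trieste,2.40,29.90,40.35,69.60,12.46,16.81,29.00
BDO TA AA,ter,Trieste,1.43,25.90,33.75,53.60,18.11,23.60,37.48
GLY FDCA AA,ter,Trieste,2.29,22.75,36.25,51.65,9.93,15.83,22.55
GLY TA AA,ter,Trieste,2.64,23.35,35.10,51.15,8.84,13.30,19.38
GLY ERY AA,ter,Trieste,1.05,9.20,17.50,32.00,8.76,16.67,30.48
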