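sample,group,solvent,enzyme,mn,mw,dispersity_printed
BDO-FDCA,co,toluene,CalB_cov,635,742,1.16
BDO-TA,co,t-BuOH,N435,694,838,1.20
BDO-AA,co,solvent-less,CalB_cov,683,729,1.06
GLY-FDCA,co,t-BuOH,CalB_cov,551,936,1.69
GLY-TA,co,t-BuOH,N435,960,1169,1.21
GLY-AA,co,solvent-less,CalB_cov,912,940,1.03
BDO FDCA AA,ter,toluene,CalB_cov,844,901,1.06
BDO TA AA,ter,toluene,N435,615,747,1.21
GLY FDCA AA,ter,t-BuOH,CalB_cov,481,551,1.25
GLY TA AA,ter,t-BuOH,N435,582,675,1.15
GLY ERY AA,ter,solvent-less,CalB_cov,845,1140,1.35
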