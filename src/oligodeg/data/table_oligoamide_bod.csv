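sample,group,inoculum,bod5,dt5,bod10,dt10,bod21,dt21
DAF,monomer,Trieste,0.01,0.10,0.05,0.36,0.05,0.37
DAF-AA,co,Trieste,0.01,0.41,0.05,1.44,0.05,1.59
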