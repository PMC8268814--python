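compound,iLOGP,XLOGP3,WLOGP,MLOGP,SILICOS_IT,virtual,experimental
NaC,2.84,2.022,2.11,3.05,2.53,1.3768,1.1
NaHC,3.06,2.8,2.11,3.05,2.53,1.5761,1.84
NaDC,3.07,3.5,3.14,3.88,3.42,2.3453,2.65
NaCDC,3.21,3.08,3.14,3.88,3.42,2.2348,2.25
NaUDC,3.14,3.08,3.14,3.88,3.42,2.346,2.2
NaHDC,3.15,2.8,3.14,3.88,3.42,2.2667,2.28
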