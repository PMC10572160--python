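mda_nmol_per_mgprot,sh_umol_per_gprot,day
4.44,150.43,0
4.84,134.09,2
5.01,124.89,4
5.99,112.16,6
6.18,104.87,8
6.74,103.25,10
6.81,101.67,12
7.24,98.17,14
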