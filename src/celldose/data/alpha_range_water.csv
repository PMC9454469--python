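# CSDA range of alpha particles in liquid water of unit density.
# Approximate transcription of standard stopping-power compilation values
# (ICRU Report 49 lineage); intermediate energies are obtained by log-log
# interpolation. Straggling and delta-ray transport are not represented
# (continuous-slowing-down, straight-line model).
energy_MeV,range_um
0.1,0.9
0.2,1.2
0.5,2.2
1.0,5.4
1.5,8.8
2.0,12.6
2.5,16.6
3.0,21.0
3.5,25.7
4.0,30.8
4.5,36.2
5.0,41.9
5.5,48.0
6.0,54.4
6.5,61.1
7.0,68.1
7.5,75.4
8.0,83.0
8.5,90.9
9.0,99.1
9.5,107.6
10.0,116.3
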