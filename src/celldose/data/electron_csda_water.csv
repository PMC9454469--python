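# CSDA range of electrons in liquid water of unit density.
# Approximate transcription of standard stopping-power compilation values
# (ICRU Report 37 lineage); provided as the selectable alternative to the
# default Cole power-law relation. Log-log interpolated between rows.
energy_MeV,range_um
0.001,0.05
0.002,0.14
0.005,0.55
0.01,2.52
0.02,8.57
0.03,17.6
0.05,43.2
0.1,143.0
0.2,449.0
0.3,836.0
0.5,1760.0
0.7,2770.0
1.0,4370.0
2.0,9785.0
3.0,15140.0
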