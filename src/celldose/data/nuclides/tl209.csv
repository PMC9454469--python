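# 209Tl principal emissions, per nuclear transition.
# Best-effort transcription (MIRD monograph / ICRP 107 lineage); values rounded.
# Beta represented by a single average-energy line.
# half_life_s: 129.7
# daughter: pb209 1.0
icode,yield,energy_MeV
beta-,1.0000,0.6590
gamma,0.9970,1.5670
gamma,0.9700,0.4650
gamma,0.8450,0.1170
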