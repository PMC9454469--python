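# 211Pb principal emissions, per nuclear transition.
# Beta represented by a single average-energy line.
# Best-effort transcription (MIRD monograph / ICRP 107 lineage); values rounded.
# half_life_s: 2166.0
# daughter: bi211 1.0
icode,yield,energy_MeV
beta-,1.0000,0.4550
gamma,0.0378,0.4049
gamma,0.0178,0.8319
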