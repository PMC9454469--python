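# 221Fr principal emissions, per nuclear transition.
# Best-effort transcription (MIRD monograph / ICRP 107 lineage); values rounded.
# half_life_s: 286.1
# daughter: at217 1.0
icode,yield,energy_MeV
alpha,0.8360,6.341
alpha,0.1510,6.126
gamma,0.1140,0.2183
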