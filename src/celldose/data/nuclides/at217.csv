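# 217At principal emissions, per nuclear transition.
# Continues into the packaged 213Bi chain (secular equilibrium).
# Best-effort transcription (MIRD monograph / ICRP 107 lineage); values rounded.
# half_life_s: 0.0323
# daughter: bi213 1.0
icode,yield,energy_MeV
alpha,0.9990,7.067
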