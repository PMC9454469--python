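# 213Po principal emissions, per nuclear transition.
# Best-effort transcription (MIRD monograph / ICRP 107 lineage); values rounded.
# half_life_s: 3.72e-6
# daughter: pb209 1.0
icode,yield,energy_MeV
alpha,1.0000,8.376
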