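# 215Po principal emissions, per nuclear transition.
# Best-effort transcription (MIRD monograph / ICRP 107 lineage); values rounded.
# half_life_s: 1.781e-3
# daughter: pb211 1.0
icode,yield,energy_MeV
alpha,0.9999,7.386
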