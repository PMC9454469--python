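# 219Rn principal emissions, per nuclear transition.
# Best-effort transcription (MIRD monograph / ICRP 107 lineage); values rounded.
# half_life_s: 3.96
# daughter: po215 1.0
icode,yield,energy_MeV
alpha,0.7940,6.819
alpha,0.1290,6.553
alpha,0.0750,6.425
gamma,0.1070,0.2712
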