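# 223Ra principal emissions, per nuclear transition.
# Best-effort transcription (MIRD monograph / ICRP 107 lineage); values rounded.
# half_life_s: 987854.0
# daughter: rn219 1.0
icode,yield,energy_MeV
alpha,0.5120,5.716
alpha,0.2520,5.607
alpha,0.0900,5.747
alpha,0.0900,5.540
gamma,0.1390,0.2694
gamma,0.1240,0.1541
xray,0.5900,0.0840
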