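# 211Bi principal emissions, per nuclear transition.
# Alpha branch (99.72%) to 207Tl; the minor beta branch (0.28%) to 211Po is
# folded into the 207Tl branch for chain purposes (negligible dosimetric effect).
# Best-effort transcription (MIRD monograph / ICRP 107 lineage); values rounded.
# half_life_s: 128.4
# daughter: tl207 1.0
icode,yield,energy_MeV
alpha,0.8340,6.623
alpha,0.1630,6.278
gamma,0.1300,0.3510
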