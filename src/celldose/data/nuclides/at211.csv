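# 211At principal emissions, per nuclear transition.
# Branches: alpha (41.8%) to 207Bi, electron capture (58.2%) to 211Po.
# The 207Bi daughter (T1/2 = 32 y) is OMITTED from the packaged chain:
# secular equilibrium with a 7.2-h parent is not physically meaningful there.
# Best-effort transcription (MIRD monograph / ICRP 107 lineage); values rounded.
# half_life_s: 25970.4
# daughter: po211 0.582
icode,yield,energy_MeV
alpha,0.4180,5.867
xray,0.7600,0.0790
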