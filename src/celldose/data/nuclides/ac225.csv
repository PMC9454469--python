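# 225Ac principal emissions, per nuclear transition.
# The many alpha groups are condensed into two representative lines.
# Best-effort transcription (MIRD monograph / ICRP 107 lineage); values rounded.
# half_life_s: 857134.0
# daughter: fr221 1.0
icode,yield,energy_MeV
alpha,0.7000,5.830
alpha,0.3000,5.723
xray,0.3000,0.0860
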