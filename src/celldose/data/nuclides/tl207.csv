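# 207Tl principal emissions, per nuclear transition. Daughter 207Pb stable.
# Beta represented by a single average-energy line.
# Best-effort transcription (MIRD monograph / ICRP 107 lineage); values rounded.
# half_life_s: 286.2
icode,yield,energy_MeV
beta-,1.0000,0.4930
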