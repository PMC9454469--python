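# 211Po principal emissions, per nuclear transition. Daughter 207Pb stable.
# Best-effort transcription (MIRD monograph / ICRP 107 lineage); values rounded.
# half_life_s: 0.516
icode,yield,energy_MeV
alpha,0.9890,7.450
alpha,0.0055,6.892
alpha,0.0055,6.570
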