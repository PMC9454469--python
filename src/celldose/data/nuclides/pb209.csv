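# 209Pb principal emissions, per nuclear transition. Daughter 209Bi treated
# as stable. Best-effort transcription (MIRD monograph / ICRP 107 lineage).
# half_life_s: 11710.8
icode,yield,energy_MeV
beta-,1.0000,0.1980
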