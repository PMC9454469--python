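# 111In principal emissions, per nuclear transition (electron capture to 111Cd,
# stable). Auger/Coster-Kronig cascade condensed into three representative
# lines preserving the approximate total Auger energy per decay (~6.7 keV).
# Best-effort transcription (MIRD monograph / ICRP 107 lineage); values rounded.
# half_life_s: 242326.0
icode,yield,energy_MeV
ic,0.0833,0.1450
ic,0.0100,0.1680
ic,0.0306,0.2190
ic,0.0060,0.2420
auger,0.1570,0.0191
auger,1.0200,0.0026
auger,2.5000,0.0004
gamma,0.9070,0.1712
gamma,0.9410,0.2454
xray,0.6900,0.0234
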