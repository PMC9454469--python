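# 213Bi principal emissions, per nuclear transition.
# Best-effort transcription from standard decay-scheme compilations
# (MIRD: Radionuclide Data and Decay Schemes / ICRP Publication 107 lineage);
# values rounded. Beta emissions are represented by a single average-energy line.
# half_life_s: 2735.4
# daughter: po213 0.9780
# daughter: tl209 0.0220
icode,yield,energy_MeV
beta-,0.9780,0.4440
alpha,0.0200,5.875
alpha,0.0020,5.549
ic,0.0130,0.3990
gamma,0.2590,0.4405
xray,0.0500,0.0790
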