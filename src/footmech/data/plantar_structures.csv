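structure,k_N_per_mm
plantar_fascia,203.3
long_short_plantar_ligament,75.9
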