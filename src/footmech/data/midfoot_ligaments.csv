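ligament,area_mm2,area_ratio
anterior_talocalcaneal,14.4,0.229
posterior_talocalcaneal,14.96,0.238
lateral_talocalcaneal,6.84,0.109
medial_talocalcaneal,14.91,0.237
interosseous_talocalcaneal,72.80,1.158
dorsal_talonavicular,35.15,0.559
interosseous_calcaneocuboid,72.80,1.158
plantar_calcaneocuboid,98.70,1.570
inferior_calcaneonavicular,9.23,0.147
superomedial_calcaneonavicular,161.00,2.560
dorsal_cuboideonavicular,13.10,0.208
plantar_cuboideonavicular,27.80,0.442
interosseous_cuboideonavicular,14.01,0.223
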