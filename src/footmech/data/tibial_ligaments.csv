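ligament,a_N,b,k_N_per_mm
anterior_talofibular,7.18,12.50,
anterior_tibiofibular,5.52,22.63,
anterior_tibiotalar,2.06,20.11,
calcaneofibular,0.20,49.63,
posterior_talofibular,0.14,44.35,
posterior_tibiofibular,6.87,20.07,
posterior_tibiotalar,1.34,28.65,
tibiocalcaneal,0.51,45.99,
tibionavicular,,,39.1
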