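# Linear attenuation coefficients (cm^-1) at 30 keV photon energy.
# Editable defaults assembled from standard tissue-property literature ranges;
# only the fat/glandular separation is load-bearing for the F:G statistic.
tissue,mu_cm_inv
background,0.0
fat,0.227
glandular,0.334
skin,0.356
artery,0.388
vein,0.386
muscle,0.370
ligament,0.347
nipple,0.352
tdlu,0.341
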