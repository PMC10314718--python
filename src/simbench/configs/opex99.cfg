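# Original clustered lumpy background parameterization (single layer,
# isotropic blob orientations).
config_name = opex99
image_size = 256
n_layers = 1
layer1.mean_cluster_count = 150
layer1.mean_blobs_per_cluster = 20
layer1.cluster_spread = 12
layer1.blob_length_x = 5
layer1.blob_length_y = 2
layer1.blob_alpha = 2.1
layer1.blob_beta = 0.5
layer1.orientation_mode = isotropic
gray.offset = 0
gray.scale = 56.2
gray.clip_low = 0
gray.clip_high = 255
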