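# Double-layer variant, isotropic orientations: a coarse structural layer
# plus a fine-texture layer, summed before gray mapping.
config_name = doubiso
image_size = 256
n_layers = 2
layer1.mean_cluster_count = 60
layer1.mean_blobs_per_cluster = 12
layer1.cluster_spread = 14
layer1.blob_length_x = 10
layer1.blob_length_y = 4
layer1.blob_alpha = 2.5
layer1.blob_beta = 0.8
layer1.orientation_mode = isotropic
layer2.mean_cluster_count = 150
layer2.mean_blobs_per_cluster = 20
layer2.cluster_spread = 8
layer2.blob_length_x = 4
layer2.blob_length_y = 1.8
layer2.blob_alpha = 2.1
layer2.blob_beta = 0.7
layer2.orientation_mode = isotropic
gray.offset = 0
gray.scale = 65.7
gray.clip_low = 0
gray.clip_high = 255
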