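# Single-layer variant with anisotropically oriented clusters: blobs in a
# cluster share a preferred direction with angular jitter.
config_name = simpori
image_size = 256
n_layers = 1
layer1.mean_cluster_count = 90
layer1.mean_blobs_per_cluster = 15
layer1.cluster_spread = 10
layer1.blob_length_x = 8
layer1.blob_length_y = 3
layer1.blob_alpha = 2.3
layer1.blob_beta = 0.75
layer1.orientation_mode = oriented
layer1.angular_jitter = 0.25
gray.offset = 0
gray.scale = 76.6
gray.clip_low = 0
gray.clip_high = 255
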