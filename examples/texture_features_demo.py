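"""The 17 per-image texture features.

Computes first-order, co-occurrence (GLCM), run-length (GLRM) and
neighborhood gray-tone difference (NGTDM) features for one clustered-lumpy
image and for its blurred/low-passed degradation, showing which features the
degradation moves most.
"""

from simbench import load_clb_config, sample_clb_image
from simbench.harness import degrade_image
from simbench.texture import FEATURE_NAMES, texture_feature_vector

img = sample_clb_image(load_clb_config("doubiso"), seed=3)
degraded = degrade_image(img, blur_sigma=2.0)

v_ref = texture_feature_vector(img).to_dict()
v_deg = texture_feature_vector(degraded).to_dict()

print(f"{'feature':>18} {'reference':>12} {'degraded':>12}")
for name in FEATURE_NAMES:
    print(f"{name:>18} {v_ref[name]:12.4g} {v_deg[name]:12.4g}")

print(
    "\nBlurring lengthens constant-gray runs (lower short-primitive emphasis,\n"
    "higher long-primitive emphasis) and smooths neighborhoods (higher NGTDM\n"
    "coarseness) -- exactly the statistics the comparison harness watches."
)
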