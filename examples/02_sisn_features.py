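"""Compute SISN slice-position features from a segmentation phantom.

A nodule of 12 mm on 5 mm slices spans ceil(12/5) = 3 axial slices; the six
SISN features summarize where that run sits in the stack, normalized by the
total slice count so every value lies in [0, 1].
"""

from lungreport import (
    GeneratorConfig,
    LocationLabel,
    MarginLabel,
    SemanticLabels,
    TextureLabel,
    compute_sisn,
    simulate_phantom,
)

labels = SemanticLabels(location=LocationLabel.RUL, texture=TextureLabel.SOLID,
                        margin=MarginLabel.LOBULATED)
stack = simulate_phantom(labels, size_mm=12.0, config=GeneratorConfig(), seed=7)
features = compute_sisn(stack)

print(f"stack: {stack.mask.shape[0]} slices of {stack.slice_thickness_mm} mm")
for name, value in features.as_dict().items():
    print(f"  {name:14s} {value:.4f}")
# ratio = labeled/total slices; first/last/peak/centroid locate the run
# (an RUL nodule lands in the top band of the stack, hence small values);
# span is the envelope, equal to ratio because the run has no gaps.
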