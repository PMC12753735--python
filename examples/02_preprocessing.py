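"""Preprocess a smear image: resize, rescale, CLAHE, augmentation.

Prints the effect of each operator.  The CLAHE step should raise the
contrast (intensity std) of the low-contrast synthetic frame; the
augmentation draw stays inside the stated parameter ranges.
"""

import numpy as np

from smearkit import (
    ClaheParams,
    ResizeSpec,
    SmearSpec,
    clahe_enhance,
    generate_smear,
    normalize_unit,
    resize_bilinear,
    sample_augmentation,
    apply_augmentation,
)

img = generate_smear(SmearSpec(seed=3)).image
print(f"input {img.shape}, intensity std {img.std():.2f}")

resized = resize_bilinear(img, ResizeSpec(224, 224))
print(f"resized to {resized.shape}; range [{resized.min()}, {resized.max()}] "
      "(bilinear interpolation never exceeds the input range)")

enhanced = clahe_enhance(resized, ClaheParams(clip_limit=2.0, tile_grid=(8, 8)))
print(f"CLAHE: std {resized.std():.2f} -> {enhanced.std():.2f}")

unit = normalize_unit(enhanced)
print(f"unit-scaled: dtype {unit.dtype}, range [{unit.min():.3f}, {unit.max():.3f}]")

t = sample_augmentation(seed=42)
print(f"sampled transform: rotation {t.rotation_deg:+.1f} deg, "
      f"shift {tuple(round(s, 3) for s in t.shift_frac)}, shear {t.shear:.3f}, "
      f"zoom {tuple(round(z, 3) for z in t.zoom)}, hflip {t.horizontal_flip}")
aug = apply_augmentation(enhanced, t)
print(f"augmented image keeps shape {aug.shape}")
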