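"""Grad-CAM localization for a classified cell.

Briefly fits the classifier on a tiny fixture, predicts one ROI and
renders the class-discriminative heatmap: channel weights are the
spatially averaged gradients of the class logit at the last conv layer,
and the rectified weighted activation sum is max-normalized to [0, 1].
High values mark the image evidence for the predicted class.
"""

import numpy as np

from smearkit import (
    LWCNNConfig,
    TrainingPolicy,
    build_lwcnn,
    compute_gradcam,
    generate_roi_arrays,
    overlay,
    predict_proba,
)
from smearkit.classifier import CLASS_NAMES
from smearkit.nn.train import fit

x, y = generate_roi_arrays(10, seed=1)
x = x.astype(np.float32) / 255.0
onehot = np.eye(9, dtype=np.float32)[y]

model = build_lwcnn(LWCNNConfig(dropout_conv=0.0, dropout_dense=0.0), seed=0)
policy = TrainingPolicy(loss="cce", max_epochs=6, batch_size=16)
fit(model, x, onehot, x, onehot, policy, seed=0)

roi = x[0]
pred = predict_proba(model, roi)
print(f"true class: {CLASS_NAMES[y[0]]}; predicted: {pred.predicted_name} "
      f"(confidence {pred.confidence:.3f})")

hm = compute_gradcam(model, roi, pred.predicted_class)
print(f"heatmap from layer {hm.layer_name!r}: range [{hm.values.min():.2f}, "
      f"{hm.values.max():.2f}]")
cell = roi.any(axis=-1)
print(f"mean attention on the cell: {hm.values[cell].mean():.3f}; "
      f"on the empty background: {hm.values[~cell].mean():.3f}")
blended = overlay((roi * 255).astype(np.uint8), hm, alpha=0.4)
print(f"overlay rendered: {blended.shape} {blended.dtype}")
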