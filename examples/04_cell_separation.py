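"""Separate two overlapping cells with the marker-controlled watershed.

Builds a union of two discs whose masks overlap, runs the full
separation stage (clean -> distance transform -> markers -> compact
flooding -> filters -> ROI extraction) and prints the region table.
The two discs should come back as two kept regions.
"""

import numpy as np

from smearkit import WatershedParams, separate_cells

yy, xx = np.mgrid[:96, :96]
mask = ((yy - 44) ** 2 + (xx - 36) ** 2 <= 13**2) | \
       ((yy - 48) ** 2 + (xx - 58) ** 2 <= 12**2)
image = np.zeros((96, 96, 3), dtype=np.uint8)
image[mask] = (228, 120, 110)

labels, rois, removed = separate_cells(image, mask, WatershedParams(), roi_size=64)

print(f"foreground pixels: {int(mask.sum())}; regions found: {labels.max()}")
print(f"kept regions: {len(rois)}, removed: {len(removed)}")
for roi in rois:
    p = roi.props
    print(f"  region {p.instance_id}: area {p.area} px, perimeter {p.perimeter:.1f}, "
          f"circularity {p.circularity:.3f} (disc-like cells measure near 0.9-1.0)")
# the ROI crops are background-zeroed, ready for the classifier
assert all((r.crop[~r.mask] == 0).all() for r in rois)
print("all ROI crops have exactly-zero background")
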