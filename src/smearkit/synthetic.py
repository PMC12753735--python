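"""Seedable synthetic blood-smear generator.

Renders round-ish cells of the nine blood-cell classes onto a pale
background with controlled pairwise overlap, a linear illumination
gradient and additive Gaussian noise, together with exact ground truth:
a per-pixel instance map and an instance-id -> class-name table.  This
gives every downstream stage (segmentation, watershed separation,
classification) a paired input/truth fixture with no external data.

Class morphologies (radii, colours, nucleus lobe counts) are fixture
defaults chosen to be mutually distinguishable; they are NOT calibrated
to real hematology and carry no diagnostic meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .classifier import CLASS_NAMES

__all__ = [
    "CellClassSpec",
    "SmearSpec",
    "SyntheticSample",
    "DEFAULT_CLASS_SPECS",
    "REFERENCE_CLASS_COUNTS",
    "PlacementError",
    "render_cell",
    "generate_smear",
    "generate_roi_arrays",
    "generate_roi_dataset",
]

#: Emulated per-class image counts of the reference distribution
#: (used when a dataset with realistic class imbalance is requested).
REFERENCE_CLASS_COUNTS = {
    "Erythrocyte": 1200,
    "Erythroblast": 1168,
    "Neutrophil": 1133,
    "Basophil": 969,
    "Eosinophil": 1186,
    "Lymphocyte": 1131,
    "Monocyte": 999,
    "Immature Granulocytes": 1134,
    "Platelet": 1204,
}

BACKGROUND_RGB = (246, 240, 235)


@dataclass(frozen=True)
class CellClassSpec:
    """Morphology of one synthetic cell class (fixture values, px / RGB)."""

    class_name: str
    radius_range: tuple  # (min, max) px, inclusive
    body_color: tuple  # mean RGB of the cytoplasm/body
    nucleus_lobes: int = 0  # 0 = anucleate
    nucleus_color: tuple = (90, 60, 140)
    nucleus_frac: float = 0.5  # nucleus size relative to cell radius
    nucleus_shape: str = "lobed"  # round | kidney | band | lobed
    granularity: float = 0.0  # texture-noise amplitude in [0, 1]
    color_jitter: float = 8.0  # per-cell RGB std

    def __post_init__(self):
        lo, hi = self.radius_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"degenerate radius_range {self.radius_range}")
        if self.nucleus_lobes < 0:
            raise ValueError("nucleus_lobes must be >= 0")
        if not 0.0 <= self.granularity <= 1.0:
            raise ValueError("granularity must lie in [0, 1]")


DEFAULT_CLASS_SPECS = {
    "Erythrocyte": CellClassSpec("Erythrocyte", (8, 10), (228, 120, 110), 0, granularity=0.05),
    "Erythroblast": CellClassSpec("Erythroblast", (9, 11), (225, 150, 150), 1,
                                  (95, 55, 135), 0.55, "round", 0.10),
    "Neutrophil": CellClassSpec("Neutrophil", (12, 14), (235, 205, 215), 3,
                                (110, 70, 150), 0.35, "lobed", 0.20),
    "Basophil": CellClassSpec("Basophil", (11, 13), (185, 160, 210), 2,
                              (70, 50, 130), 0.40, "lobed", 0.80),
    "Eosinophil": CellClassSpec("Eosinophil", (12, 14), (240, 170, 140), 2,
                                (120, 80, 160), 0.38, "lobed", 0.70),
    "Lymphocyte": CellClassSpec("Lymphocyte", (9, 11), (200, 210, 235), 1,
                                (85, 70, 160), 0.80, "round", 0.10),
    "Monocyte": CellClassSpec("Monocyte", (14, 16), (215, 210, 230), 1,
                              (120, 100, 170), 0.70, "kidney", 0.15),
    "Immature Granulocytes": CellClassSpec("Immature Granulocytes", (12, 14), (225, 190, 210), 1,
                                           (100, 80, 150), 0.60, "band", 0.30),
    "Platelet": CellClassSpec("Platelet", (3, 5), (175, 140, 200), 0, granularity=0.40),
}
assert set(DEFAULT_CLASS_SPECS) == set(CLASS_NAMES)
# pairwise distinguishability of the nine specs
_sigs = {(s.radius_range, s.body_color, s.nucleus_lobes) for s in DEFAULT_CLASS_SPECS.values()}
assert len(_sigs) == len(DEFAULT_CLASS_SPECS), "class specs are not pairwise distinguishable"


@dataclass(frozen=True)
class SmearSpec:
    """Conditions for one synthetic smear frame."""

    height: int = 256
    width: int = 256
    cells_per_class: dict = field(default_factory=lambda: {name: 2 for name in CLASS_NAMES})
    overlap_fraction: float = 0.2
    illumination_gradient: float = 0.15  # max relative brightness change
    noise_sigma: float = 4.0  # additive Gaussian std on the [0,255] scale
    seed: int = 0
    attempt_cap: int = 100  # placement attempts per cell before failing
    class_specs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SPECS))

    def __post_init__(self):
        if any(v < 0 for v in self.cells_per_class.values()):
            raise ValueError("cell counts must be >= 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SyntheticSample:
    image: np.ndarray  # (H, W, 3) uint8
    instances: np.ndarray  # (H, W) int32; 0 = background
    labels: dict  # instance id -> class name
    achieved_overlap_fraction: float
    spec: SmearSpec


class PlacementError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# single-cell rendering
# ---------------------------------------------------------------------------

def _disc(side: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[:side, :side]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def render_cell(spec: CellClassSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Render one cell sprite on a zeroed canvas.

    Returns ``(sprite, mask)``: sprite is (S,S,3) uint8, exactly zero
    outside ``mask``; equal (spec, seed) pairs give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.radius_range
    r = float(rng.uniform(lo, hi))
    side = 2 * int(np.ceil(r)) + 3
    c = side / 2.0 - 0.5
    mask = _disc(side, c, c, r)
    body = np.array(spec.body_color, dtype=np.float64)
    if spec.granularity > 0 or spec.nucleus_lobes > 0:
        body = body + rng.normal(0.0, spec.color_jitter, 3)
    img = np.zeros((side, side, 3), dtype=np.float64)
    img[mask] = body
    if spec.nucleus_lobes > 0:
        nuc = _nucleus_mask(spec, rng, side, c, r) & mask
        img[nuc] = np.array(spec.nucleus_color, dtype=np.float64) + rng.normal(0.0, 4.0, 3)
    if spec.granularity > 0:
        tex = rng.normal(0.0, 40.0 * spec.granularity, (side, side, 1))
        img[mask] += np.broadcast_to(tex, img.shape)[mask]
    img = np.clip(img, 0, 255)
    img[~mask] = 0
    return img.astype(np.uint8), mask


def _nucleus_mask(spec, rng, side, c, r) -> np.ndarray:
    rn = spec.nucleus_frac * r
    if spec.nucleus_shape == "round":
        return _disc(side, c, c, rn)
    if spec.nucleus_shape == "kidney":
        body = _disc(side, c, c, rn)
        ang = rng.uniform(0, 2 * np.pi)
        by, bx = c + 0.9 * rn * np.sin(ang), c + 0.9 * rn * np.cos(ang)
        return body & ~_disc(side, by, bx, 0.7 * rn)
    if spec.nucleus_shape == "band":
        ang0 = rng.uniform(0, 2 * np.pi)
        out = np.zeros((side, side), dtype=bool)
        for k in range(3):  # three overlapping discs along an arc
            a = ang0 + k * 0.9
            oy, ox = c + 0.45 * r * np.sin(a), c + 0.45 * r * np.cos(a)
            out |= _disc(side, oy, ox, 0.55 * rn)
        return out
    # lobed: nucleus_lobes discs arranged around the centre
    out = np.zeros((side, side), dtype=bool)
    ang0 = rng.uniform(0, 2 * np.pi)
    offset = 0.0 if spec.nucleus_lobes == 1 else 0.40 * r
    for k in range(spec.nucleus_lobes):
        a = ang0 + 2 * np.pi * k / spec.nucleus_lobes
        oy, ox = c + offset * np.sin(a), c + offset * np.cos(a)
        out |= _disc(side, oy, ox, spec.nucleus_frac * r)
    return out


# ---------------------------------------------------------------------------
# whole-smear compositing
# ---------------------------------------------------------------------------

def _paste(canvas, instances, sprite, mask, top, left, inst_id):
    s = sprite.shape[0]
    region = (slice(top, top + s), slice(left, left + s))
    canvas[region][mask] = sprite[mask]
    instances[region][mask] = inst_id


def _connected(mask: np.ndarray) -> bool:
    if not mask.any():
        return False
    _, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    return n == 1


def generate_smear(spec: SmearSpec) -> SyntheticSample:
    """Generate one smear with ground-truth instance map and labels.

    Cells are placed by rejection sampling with a per-cell attempt cap.
    A subset of cells of size ``round(overlap_fraction * n)`` (paired off)
    is placed with the centre-distance constraint relaxed so each pair's
    masks intersect; all other cells are mutually disjoint.  Illumination
    and noise are applied after compositing, so the instance map is exact.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    canvas = np.empty((h, w, 3), dtype=np.uint8)
    canvas[:] = BACKGROUND_RGB
    instances = np.zeros((h, w), dtype=np.int32)

    order = [name for name in CLASS_NAMES for _ in range(spec.cells_per_class.get(name, 0))]
    rng.shuffle(order)
    n_total = len(order)
    if n_total == 0:
        return SyntheticSample(_finish(canvas, rng, spec), instances, {}, 0.0, spec)

    n_pairs = min(int(round(spec.overlap_fraction * n_total / 2.0)), n_total // 2)
    # the last n_pairs cells are placed as overlappers, so a non-overlapped
    # partner always exists by the time each one is placed
    overlap_slots = set(range(n_total - n_pairs, n_total))

    placed = []  # dicts: cy, cx, r, id, overlapped
    labels = {}
    sprites = {}
    next_id = 1
    for slot, name in enumerate(order):
        cspec = spec.class_specs[name]
        sprite, mask = render_cell(cspec, int(rng.integers(2**31)))
        s = sprite.shape[0]
        r = s / 2.0 - 1.5
        want_overlap = slot in overlap_slots and any(not p["overlapped"] for p in placed)
        ok = False
        # overlappers that cannot be attached (crowded partner neighbourhood)
        # fall back to isolated placement in the second half of the budget;
        # the achieved overlap fraction reports what was actually realised
        for attempt in range(spec.attempt_cap):
            if want_overlap and attempt >= spec.attempt_cap // 2:
                want_overlap = False
            if want_overlap:
                cands = [p for p in placed if not p["overlapped"]]
                partner = cands[int(rng.integers(len(cands)))]
                d_lo = abs(partner["r"] - r) + 3.0
                d_hi = 0.85 * (partner["r"] + r)
                if d_lo >= d_hi:
                    d_lo = 0.5 * d_hi
                d = rng.uniform(d_lo, d_hi)
                a = rng.uniform(0, 2 * np.pi)
                cy = partner["cy"] + d * np.sin(a)
                cx = partner["cx"] + d * np.cos(a)
            else:
                cy = rng.uniform(r + 1, h - r - 2)
                cx = rng.uniform(r + 1, w - r - 2)
            if not (r + 1 <= cy <= h - r - 2 and r + 1 <= cx <= w - r - 2):
                continue
            conflict = False
            for p in placed:
                if want_overlap and p is partner:
                    continue
                dd = np.hypot(p["cy"] - cy, p["cx"] - cx)
                if dd < p["r"] + r + 2.0:
                    conflict = True
                    break
            if conflict:
                continue
            top = int(round(cy - s / 2.0 + 0.5))
            left = int(round(cx - s / 2.0 + 0.5))
            snapshot = (canvas.copy(), instances.copy()) if want_overlap else None
            _paste(canvas, instances, sprite, mask, top, left, next_id)
            if want_overlap:
                if not (_connected(instances == partner["id"]) and (instances == partner["id"]).any()):
                    canvas[:], instances[:] = snapshot  # partner broken; retry
                    continue
                if not np.any(instances[instances == next_id]) or \
                        not _mask_intersects(partner, cy, cx, r):
                    canvas[:], instances[:] = snapshot
                    continue
                partner["overlapped"] = True
            placed.append({"cy": cy, "cx": cx, "r": r, "id": next_id,
                           "overlapped": bool(want_overlap)})
            labels[next_id] = name
            sprites[next_id] = (sprite, mask, top, left)
            next_id += 1
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place a {name!r} cell after {spec.attempt_cap} attempts "
                f"on a {h}x{w} canvas"
            )
    achieved = sum(1 for p in placed if p["overlapped"]) / n_total
    image = _finish(canvas, rng, spec)
    return SyntheticSample(image, instances, labels, achieved, spec)


def generate_smear_retry(spec: SmearSpec, retries: int = 5) -> SyntheticSample:
    """Like :func:`generate_smear`, but on a placement failure the frame is
    regenerated with a deterministically bumped seed (dense frames can
    genuinely lack room for the last large cell under rejection sampling).
    Raises the original error if every retry fails."""
    from dataclasses import replace as _replace

    last: PlacementError | None = None
    for bump in range(retries):
        try:
            return generate_smear(_replace(spec, seed=(spec.seed + bump * 10_000_019) % 2**31))
        except PlacementError as e:
            last = e
    raise last


def _mask_intersects(partner, cy, cx, r) -> bool:
    return np.hypot(partner["cy"] - cy, partner["cx"] - cx) < partner["r"] + r


def _finish(canvas: np.ndarray, rng: np.random.Generator, spec: SmearSpec) -> np.ndarray:
    img = canvas.astype(np.float64)
    if spec.illumination_gradient > 0:
        h, w = img.shape[:2]
        ang = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[:h, :w]
        t = (yy * np.sin(ang) + xx * np.cos(ang)).astype(np.float64)
        t = (t - t.min()) / max(t.max() - t.min(), 1e-9)
        img *= (1.0 + spec.illumination_gradient * (t - 0.5))[..., None]
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# single-cell ROI dataset (classifier fixture)
# ---------------------------------------------------------------------------

def generate_roi_arrays(
    n_per_class: int | dict,
    roi_size: int = 64,
    seed: int = 0,
    class_specs: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """In-memory balanced (or per-class-count) single-cell ROI dataset.

    Returns ``(x, y)``: x is (N, roi_size, roi_size, 3) uint8 with zeroed
    background (mirroring the watershed extraction contract), y integer
    labels indexing :data:`smearkit.classifier.CLASS_NAMES`.
    """
    class_specs = class_specs or DEFAULT_CLASS_SPECS
    if isinstance(n_per_class, int):
        if n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        counts = {name: n_per_class for name in CLASS_NAMES}
    else:
        counts = dict(n_per_class)
    max_d = max(2 * s.radius_range[1] + 4 for s in class_specs.values())
    if roi_size < max_d:
        raise ValueError(f"roi_size {roi_size} smaller than the largest cell ({max_d} px)")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for ci, name in enumerate(CLASS_NAMES):
        cspec = class_specs[name]
        for _ in range(counts.get(name, 0)):
            sprite, mask = render_cell(cspec, int(rng.integers(2**31)))
            canvas = np.zeros((roi_size, roi_size, 3), dtype=np.uint8)
            s = sprite.shape[0]
            slack = roi_size - s
            top = slack // 2 + int(rng.integers(-slack // 4, slack // 4 + 1)) if slack > 4 else slack // 2
            left = slack // 2 + int(rng.integers(-slack // 4, slack // 4 + 1)) if slack > 4 else slack // 2
            canvas[top : top + s, left : left + s][mask] = sprite[mask]
            xs.append(canvas)
            ys.append(ci)
    return np.stack(xs), np.asarray(ys)


def generate_roi_dataset(
    out_dir: str | Path,
    n_per_class: int | dict = 100,
    roi_size: int = 64,
    seed: int = 0,
    class_specs: dict | None = None,
) -> pd.DataFrame:
    """Write a single-cell ROI dataset to ``out_dir/rois/<class>/`` with a
    manifest CSV (path, class, instance_id, seed); exact class balance."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    x, y = generate_roi_arrays(n_per_class, roi_size=roi_size, seed=seed, class_specs=class_specs)
    rows = []
    counters = {name: 0 for name in CLASS_NAMES}
    for img, ci in zip(x, y):
        name = CLASS_NAMES[ci]
        counters[name] += 1
        rel = Path("rois") / name.replace(" ", "_") / f"{name.replace(' ', '_')}_{counters[name]:04d}.png"
        path = out_dir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        iio.imwrite(path, img)
        rows.append({"path": str(rel), "class": name,
                     "instance_id": counters[name], "seed": seed})
    manifest = pd.DataFrame(rows, columns=["path", "class", "instance_id", "seed"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def write_smear_dataset(out_dir: str | Path, specs: list[SmearSpec]) -> pd.DataFrame:
    """Write smear images (PNG), instance maps (16-bit PNG) and a labels CSV."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(specs):
        sample = generate_smear(spec)
        iio.imwrite(out_dir / "images" / f"smear_{i:04d}.png", sample.image)
        iio.imwrite(out_dir / "masks" / f"smear_{i:04d}.png",
                    sample.instances.astype(np.uint16))
        for inst_id, name in sample.labels.items():
            rows.append({"image": f"smear_{i:04d}.png", "instance_id": inst_id,
                         "class": name, "seed": spec.seed})
    df = pd.DataFrame(rows, columns=["image", "instance_id", "class", "seed"])
    df.to_csv(out_dir / "labels.csv", index=False)
    return df
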