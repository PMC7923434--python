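"""Seeded generator of HEp-2-like labeled image sets.

Renders single-cell grayscale images that reproduce the statistical
structure the classification method targets, without any real microscopy
data: six staining-pattern motifs (homogeneous, speckled, nucleolar,
centromere, nuclear membrane, Golgi), a bimodal positive/negative
fluorescence intensity within every class, Gaussian pixel noise, and
configurable class imbalance emulating the rarity of the Golgi and
nuclear-membrane patterns in real training sets.

The generator is a statistical stand-in, not a simulator of
immunofluorescence physics.  Motif constants are fixed; class difficulty
is deliberately uneven — the Golgi motif is a partial membrane arc, so it
is easily confused with the nuclear-membrane ring, mirroring the
confusion structure real datasets exhibit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data_pipeline import CellImage, Dataset

MOTIFS = ("homogeneous", "speckled", "fine_speckled", "coarse_speckled",
          "nucleolar", "centromere", "nuclear_membrane", "golgi")

#: Per-class training-set sizes of the large target corpus the imbalance
#: emulates: four common patterns at 2100 and the two rare ones at 814
#: (nuclear membrane) and 375 (Golgi).
REFERENCE_COUNTS = {
    "homogeneous": 2100,
    "speckled": 2100,
    "nucleolar": 2100,
    "centromere": 2100,
    "nuclear_membrane": 814,
    "golgi": 375,
}

TARGET_CLASSES = ("homogeneous", "speckled", "nucleolar", "centromere",
                  "nuclear_membrane", "golgi")
SOURCE_CLASSES = ("homogeneous", "fine_speckled", "coarse_speckled",
                  "nucleolar", "centromere")


@dataclass
class SynthSpec:
    """Recipe for one synthetic dataset.

    classes: (name, motif, count) triples, rendered in order.
    positive_fraction: share of images drawn in the bright (positive
        fluorescence) mode; the rest use the dim negative mode.
    intensity_means: foreground gray levels (positive_mode, negative_mode).
    noise_sd: additive Gaussian pixel noise, in [0,1] gray units.
    """

    classes: tuple[tuple[str, str, int], ...]
    image_side: int = 112
    positive_fraction: float = 0.5
    intensity_means: tuple[float, float] = (0.78, 0.38)
    noise_sd: float = 0.04
    seed: int = 0
    id_prefix: str = "syn"

    def validate(self) -> None:
        pos, neg = self.intensity_means
        if not pos > neg:
            raise ValueError("positive mode must be brighter than negative mode")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        for name, motif, count in self.classes:
            if motif not in MOTIFS:
                raise ValueError(f"unknown motif {motif!r} for class {name!r}; "
                                 f"known motifs: {', '.join(MOTIFS)}")
            if count < 0:
                raise ValueError(f"negative count for class {name!r}")
        if self.image_side < 16 or self.image_side % 2:
            raise ValueError("image_side must be even and >= 16")


_BG = 0.06  # dark background gray level


def _disk_points(rng: np.random.Generator, n: int, cx: float, cy: float,
                 rmax: float) -> tuple[np.ndarray, np.ndarray]:
    theta = rng.uniform(0, 2 * np.pi, n)
    rad = rmax * np.sqrt(rng.uniform(0, 1, n))
    return cx + rad * np.cos(theta), cy + rad * np.sin(theta)


def _add_dots(canvas: np.ndarray, xx: np.ndarray, yy: np.ndarray,
              xs: np.ndarray, ys: np.ndarray, radius: float, value: float) -> None:
    r2 = radius * radius
    s = canvas.shape[0]
    ir = int(np.ceil(radius)) + 1
    for x, y in zip(xs, ys):
        x0, x1 = max(0, int(x) - ir), min(s, int(x) + ir + 1)
        y0, y1 = max(0, int(y) - ir), min(s, int(y) + ir + 1)
        patch = (xx[y0:y1, x0:x1] - x) ** 2 + (yy[y0:y1, x0:x1] - y) ** 2 <= r2
        region = canvas[y0:y1, x0:x1]
        region[patch] = np.maximum(region[patch], value)


def _add_blobs(canvas: np.ndarray, xx: np.ndarray, yy: np.ndarray,
               xs: np.ndarray, ys: np.ndarray, sigma: float, value: float) -> None:
    for x, y in zip(xs, ys):
        g = np.exp(-(((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma * sigma)))
        np.maximum(canvas, _BG + (value - _BG) * g, out=canvas)


def render_cell(motif: str, fg: float, side: int,
                rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    """Render one cell of the given motif at foreground level ``fg``."""
    ax = np.arange(side, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    cx = side / 2 + rng.uniform(-0.04, 0.04) * side
    cy = side / 2 + rng.uniform(-0.04, 0.04) * side
    r0 = side * rng.uniform(0.33, 0.40)
    dist = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    disk = dist <= r0

    canvas = np.full((side, side), _BG)
    base = _BG + 0.28 * (fg - _BG)  # dim cytoplasm level inside the cell

    if motif == "homogeneous":
        canvas[disk] = fg
    elif motif in ("speckled", "fine_speckled", "coarse_speckled"):
        canvas[disk] = base
        n, r = {"speckled": (22, 0.040), "fine_speckled": (60, 0.020),
                "coarse_speckled": (10, 0.065)}[motif]
        xs, ys = _disk_points(rng, n, cx, cy, 0.85 * r0)
        _add_dots(canvas, xx, yy, xs, ys, r * side, fg)
    elif motif == "nucleolar":
        canvas[disk] = base
        nb = rng.integers(2, 6)
        xs, ys = _disk_points(rng, nb, cx, cy, 0.55 * r0)
        _add_blobs(canvas, xx, yy, xs, ys, 0.09 * side, fg)
    elif motif == "centromere":
        canvas[disk] = base
        nd = rng.integers(30, 41)
        xs, ys = _disk_points(rng, nd, cx, cy, 0.85 * r0)
        _add_dots(canvas, xx, yy, xs, ys, 0.016 * side, fg)
    elif motif == "nuclear_membrane":
        canvas[disk] = base
        ring = np.abs(dist - r0) <= 0.025 * side
        canvas[ring] = fg
    elif motif == "golgi":
        canvas[disk] = base
        # faint partial membrane arc plus an off-centre blob clump: sits
        # between the nuclear-membrane ring and the nucleolar blobs in
        # appearance, which makes it genuinely ambiguous when undersampled
        theta0 = rng.uniform(0, 2 * np.pi)
        span = rng.uniform(0.45, 0.75) * np.pi
        angle = np.arctan2(yy - cy, xx - cx)
        ddiff = np.abs((angle - theta0 + np.pi) % (2 * np.pi) - np.pi)
        arc = (np.abs(dist - r0) <= 0.022 * side) & (ddiff <= span / 2)
        canvas[arc] = base + 0.85 * (fg - base)
        nb = rng.integers(2, 5)
        blob_theta = theta0 + rng.uniform(-span / 3, span / 3, nb)
        blob_rad = r0 * rng.uniform(0.5, 0.75, nb)
        _add_blobs(canvas, xx, yy, cx + blob_rad * np.cos(blob_theta),
                   cy + blob_rad * np.sin(blob_theta), 0.055 * side, fg)
    else:
        raise ValueError(f"unknown motif {motif!r}")

    canvas = ndimage.gaussian_filter(canvas, sigma=0.004 * side + 0.4)
    canvas = canvas + rng.normal(0.0, noise_sd, canvas.shape)
    return np.clip(canvas, 0.0, 1.0).astype(np.float32)


def generate(spec: SynthSpec) -> Dataset:
    """Render the full dataset described by ``spec``; fully seed-determined."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pos, neg = spec.intensity_means
    items = []
    for name, motif, count in spec.classes:
        for i in range(count):
            fg = pos if rng.random() < spec.positive_fraction else neg
            pixels = render_cell(motif, fg, spec.image_side, rng, spec.noise_sd)
            items.append(CellImage(pixels=pixels, label=name,
                                   source_id=f"{spec.id_prefix}_{name}_{i:05d}"))
    return Dataset(items=items, class_names=[c[0] for c in spec.classes])


def imbalanced_counts(n_total: int,
                      reference: dict[str, int] | None = None) -> dict[str, int]:
    """Split ``n_total`` across the six target classes at the reference
    imbalance ratios (largest-remainder rounding, so counts sum exactly)."""
    ref = reference or REFERENCE_COUNTS
    total_ref = sum(ref.values())
    raw = {k: n_total * v / total_ref for k, v in ref.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    remainder = n_total - sum(counts.values())
    order = sorted(ref, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:remainder]:
        counts[k] += 1
    return counts


def target_spec(n_total: int = 3000, image_side: int = 112, seed: int = 0,
                id_prefix: str = "tgt") -> SynthSpec:
    """Six-class imbalanced dataset spec mirroring the target corpus."""
    counts = imbalanced_counts(n_total)
    classes = tuple((name, name, counts[name]) for name in TARGET_CLASSES)
    return SynthSpec(classes=classes, image_side=image_side, seed=seed,
                     id_prefix=id_prefix)


def source_spec(n_total: int = 900, image_side: int = 112, seed: int = 0,
                id_prefix: str = "src") -> SynthSpec:
    """Balanced five-class source dataset spec: no Golgi, and the speckled
    pattern split into fine and coarse variants — the domain shift between
    the small pretraining corpus and the large target corpus."""
    per = n_total // len(SOURCE_CLASSES)
    counts = [per] * len(SOURCE_CLASSES)
    for i in range(n_total - per * len(SOURCE_CLASSES)):
        counts[i] += 1
    classes = tuple((name, name, c) for name, c in zip(SOURCE_CLASSES, counts))
    return SynthSpec(classes=classes, image_side=image_side, seed=seed,
                     id_prefix=id_prefix)


def make_source_target_pair(spec: SynthSpec | None = None, *,
                            source_total: int = 900, target_total: int = 3000,
                            image_side: int = 112, seed: int = 0
                            ) -> tuple[Dataset, Dataset]:
    """Generate a (source, target) dataset pair for cross-modal transfer.

    The source has 5 classes (no Golgi; speckled split fine/coarse), the
    target the 6 merged classes; generation seeds and id prefixes are
    disjoint so no image is shared.
    """
    if spec is not None:
        side = spec.image_side
        seed = spec.seed
    else:
        side = image_side
    src = generate(source_spec(source_total, side, seed=seed, id_prefix="src"))
    tgt = generate(target_spec(target_total, side, seed=seed + 1, id_prefix="tgt"))
    return src, tgt
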