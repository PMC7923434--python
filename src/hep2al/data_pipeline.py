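"""Image and manifest IO, normalization, resizing and rotation augmentation.

Cell images are single grayscale channels scaled to [0, 1].  A dataset is
described by a CSV manifest with columns ``path,label[,intensity]``; image
files are PNG or TIFF, 8- or 16-bit.  RGB inputs are collapsed to
grayscale with Rec. 601 luminance weights.  All images are resized to a
common square side (112 by default) with bicubic interpolation, matching
the resolution the downstream architecture expects.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

#: Label value of a pool image whose annotation has not been purchased yet.
UNLABELED = "<unlabeled>"

DEFAULT_INPUT_SIDE = 112

_REC601 = np.array([0.299, 0.587, 0.114], dtype=np.float64)


@dataclass
class CellImage:
    """One grayscale cell image with its label and provenance key."""

    pixels: np.ndarray  # float32, [0, 1], shape (H, W)
    label: str          # class name or UNLABELED
    source_id: str

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def validate(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError(f"{self.source_id}: pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError(f"{self.source_id}: non-finite pixels")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError(f"{self.source_id}: pixels outside [0, 1]")


@dataclass
class Dataset:
    """An ordered collection of cell images plus the class vocabulary."""

    items: list[CellImage]
    class_names: list[str]
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        ids = [im.source_id for im in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate source_id in dataset")
        for im in self.items:
            if im.label != UNLABELED and im.label not in self.class_names:
                raise ValueError(f"label {im.label!r} of {im.source_id} not in class_names")
        self._index = {sid: i for i, sid in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.items)

    def by_id(self, source_id: str) -> CellImage:
        return self.items[self._index[source_id]]

    def ids(self) -> list[str]:
        return [im.source_id for im in self.items]

    def pixels_array(self) -> np.ndarray:
        """Stack all images into a (n, H, W) float32 array."""
        return np.stack([im.pixels for im in self.items]).astype(np.float32)

    def label_indices(self) -> np.ndarray:
        """Integer class indices; -1 for unlabeled images."""
        lut = {name: i for i, name in enumerate(self.class_names)}
        return np.array([lut.get(im.label, -1) for im in self.items], dtype=np.int64)

    def subset(self, ids: list[str]) -> "Dataset":
        return Dataset([self.by_id(s) for s in ids], list(self.class_names))


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) RGB array to luminance; pass (H, W) through."""
    if arr.ndim == 3:
        return arr[..., :3] @ _REC601
    return arr.astype(np.float64)


def _read_image(path: str) -> np.ndarray:
    """Read a PNG/TIFF as float64 in [0, 1], dividing by the container max."""
    with Image.open(path) as img:
        arr = np.asarray(img)
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype in (np.uint16, np.int32):  # PIL 'I;16' loads as int32
        scale = 65535.0
    else:
        scale = 1.0
    gray = to_grayscale(arr.astype(np.float64))
    return np.clip(gray / scale, 0.0, 1.0)


def resize_bicubic(pixels: np.ndarray, target_size: int) -> np.ndarray:
    """Bicubic resize of a grayscale image to target_size x target_size."""
    if pixels.shape == (target_size, target_size):
        return pixels.astype(np.float32)
    img = Image.fromarray(pixels.astype(np.float32), mode="F")
    out = img.resize((target_size, target_size), resample=Image.BICUBIC)
    return np.clip(np.asarray(out, dtype=np.float32), 0.0, 1.0)


def load_manifest(manifest_path: str, image_root: str | None = None,
                  target_size: int = DEFAULT_INPUT_SIDE,
                  class_names: list[str] | None = None) -> Dataset:
    """Load a ``path,label[,intensity]`` CSV manifest into a Dataset.

    Images are read as grayscale, scaled to [0, 1] and resized to
    ``target_size`` with bicubic interpolation.  Row order is preserved and
    the row path doubles as the stable ``source_id``.

    Parameters
    ----------
    manifest_path : CSV file with a header containing at least path,label.
    image_root : directory that relative image paths are resolved against
        (defaults to the manifest's own directory).
    class_names : explicit class vocabulary; rows with labels outside it
        are reported as errors.  When omitted, the sorted set of manifest
        labels (minus UNLABELED) is used.
    """
    df = pd.read_csv(manifest_path)
    for col in ("path", "label"):
        if col not in df.columns:
            raise ValueError(f"manifest {manifest_path} lacks required column {col!r}")
    root = image_root if image_root is not None else os.path.dirname(os.path.abspath(manifest_path))

    labels = [str(v) for v in df["label"]]
    if class_names is None:
        class_names = sorted({v for v in labels if v != UNLABELED})
    else:
        bad = [(i, v) for i, v in enumerate(labels)
               if v != UNLABELED and v not in class_names]
        if bad:
            rows = ", ".join(f"row {i}: {v!r}" for i, v in bad[:10])
            raise ValueError(f"manifest labels outside class_names: {rows}")

    items = []
    for row_path, label in zip(df["path"], labels):
        full = row_path if os.path.isabs(row_path) else os.path.join(root, row_path)
        if not os.path.exists(full):
            raise FileNotFoundError(f"image listed in manifest not found: {full}")
        pixels = resize_bicubic(_read_image(full), target_size)
        items.append(CellImage(pixels=pixels, label=label, source_id=str(row_path)))
    return Dataset(items=items, class_names=list(class_names))


def rotate_image(pixels: np.ndarray, angle_degrees: float) -> np.ndarray:
    """Rotate about the image centre.

    Right-angle rotations are exact (``np.rot90``); any other angle uses
    bilinear resampling with reflect padding, which avoids the dark corner
    wedges plain zero padding would introduce on roughly centred cells.
    """
    a = angle_degrees % 360.0
    if a == 0.0:
        return pixels.copy()
    if a in (90.0, 180.0, 270.0):
        return np.ascontiguousarray(np.rot90(pixels, k=int(a // 90)))
    return ndimage.rotate(pixels, a, reshape=False, order=1,
                          mode="reflect").astype(pixels.dtype)


def rotation_augment(img: CellImage, step_degrees: float = 18.0) -> list[CellImage]:
    """All rotations of ``img`` at multiples of ``step_degrees`` in [0, 360).

    A step of 18 degrees yields 20 images and thus a 20x expansion of a
    training set.  The 0-degree copy equals the input exactly.
    """
    if img.height != img.width:
        raise ValueError("rotation_augment requires a square image")
    if step_degrees <= 0 or (360.0 / step_degrees) != int(360.0 / step_degrees):
        raise ValueError(f"step_degrees must evenly divide 360, got {step_degrees}")
    n = int(360.0 / step_degrees)
    out = []
    for i in range(n):
        angle = i * step_degrees
        rotated = rotate_image(img.pixels, angle)
        out.append(CellImage(pixels=np.clip(rotated, 0.0, 1.0).astype(np.float32),
                             label=img.label,
                             source_id=f"{img.source_id}@rot{int(angle)}" if i else img.source_id))
    return out


def augment_dataset(ds: Dataset, step_degrees: float = 18.0) -> Dataset:
    """Apply rotation augmentation to every image of a labeled dataset."""
    items = [aug for im in ds.items for aug in rotation_augment(im, step_degrees)]
    return Dataset(items=items, class_names=list(ds.class_names))
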