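"""Shared fixtures: small seeded synthetic datasets and manifest writers.

Everything is generated at test time; image side 32 keeps the unit suite
fast while exercising the full pipeline (32 -> 16x16 planes -> 8 -> 4).
"""

import numpy as np
import pytest
from PIL import Image

from hep2al.data_pipeline import CellImage, Dataset
from hep2al.synthetic_data import SynthSpec, TARGET_CLASSES, generate

SMALL_SIDE = 32


@pytest.fixture(scope="session")
def tiny_target() -> Dataset:
    """Six-class dataset, 8 images per class, side 32."""
    spec = SynthSpec(classes=tuple((n, n, 8) for n in TARGET_CLASSES),
                     image_side=SMALL_SIDE, seed=11, id_prefix="tt")
    return generate(spec)


@pytest.fixture(scope="session")
def tiny_source() -> Dataset:
    """Five-class balanced source dataset (no golgi), side 32."""
    from hep2al.synthetic_data import SOURCE_CLASSES
    spec = SynthSpec(classes=tuple((n, n, 8) for n in SOURCE_CLASSES),
                     image_side=SMALL_SIDE, seed=12, id_prefix="ts")
    return generate(spec)


@pytest.fixture
def manifest_dir(tmp_path):
    """Write a 3-image PNG dataset plus manifest; returns (dir, manifest)."""
    rng = np.random.default_rng(3)
    rows = ["path,label"]
    for i, label in enumerate(["homogeneous", "speckled", "homogeneous"]):
        arr = (rng.random((90, 90)) * 255).astype(np.uint8)
        name = f"cell_{i}.png"
        Image.fromarray(arr, mode="L").save(tmp_path / name)
        rows.append(f"{name},{label}")
    manifest = tmp_path / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return tmp_path, manifest


def make_images(n: int, side: int, seed: int) -> np.ndarray:
    return np.random.default_rng(seed).random((n, side, side)).astype(np.float32)


def as_dataset(pixels: np.ndarray, labels: list[str],
               class_names: list[str] | None = None, prefix: str = "im") -> Dataset:
    items = [CellImage(pixels=p, label=lab, source_id=f"{prefix}{i:03d}")
             for i, (p, lab) in enumerate(zip(pixels, labels))]
    return Dataset(items=items,
                   class_names=class_names or sorted(set(labels)))
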