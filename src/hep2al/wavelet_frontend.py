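"""Level-1 2D discrete wavelet transform front end.

Each image is decomposed once: the approximation plane ``A`` carries the
low-frequency content (which homogenises the gray level between positive
and negative fluorescence intensity images of the same class), and ``D``
is the element-wise sum of the horizontal, vertical and diagonal detail
planes, folding every high-frequency component — cell shape, boundaries,
internal gray variation — into a single channel.  ``A`` and ``D`` are the
two inputs of the parallel residual networks.

Boundary handling is periodization, so a 112x112 image yields exactly
56x56 coefficient planes.  The default wavelet is the orthonormal Haar
(db1); planes are passed on unnormalised — the networks' first batch
normalization layers absorb scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .data_pipeline import CellImage, Dataset

DEFAULT_WAVELET = "haar"
_DWT_MODE = "periodization"


@dataclass
class WaveletPair:
    """Approximation plane A and summed-details plane D for one image."""

    A: np.ndarray
    D: np.ndarray

    @property
    def side(self) -> int:
        return self.A.shape[0]

    def validate(self) -> None:
        if self.A.shape != self.D.shape:
            raise ValueError("A and D must share a shape")
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.D))):
            raise ValueError("non-finite wavelet coefficients")


def _check_wavelet(wavelet_name: str) -> None:
    if wavelet_name not in pywt.wavelist(kind="discrete"):
        families = ", ".join(pywt.families(short=True))
        raise ValueError(
            f"unknown wavelet {wavelet_name!r}; supported discrete families: {families}")


def dwt_decompose(img: CellImage | np.ndarray,
                  wavelet_name: str = DEFAULT_WAVELET) -> WaveletPair:
    """Single-level 2D-DWT of a square, even-sided grayscale image.

    Returns the approximation plane and the element-wise sum of the three
    detail planes, each of side ``input side / 2``.
    """
    pixels = img.pixels if isinstance(img, CellImage) else np.asarray(img)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError(f"expected a square 2-D image, got shape {pixels.shape}")
    if pixels.shape[0] % 2:
        raise ValueError(f"image side must be even (pad upstream), got {pixels.shape[0]}")
    _check_wavelet(wavelet_name)
    a, (h, v, d) = pywt.dwt2(pixels.astype(np.float64), wavelet_name, mode=_DWT_MODE)
    return WaveletPair(A=a.astype(np.float32), D=(h + v + d).astype(np.float32))


def batch_decompose(ds: Dataset | np.ndarray,
                    wavelet_name: str = DEFAULT_WAVELET) -> tuple[np.ndarray, np.ndarray]:
    """Decompose every image, preserving order.

    Returns two stacks of shape ``(n, side/2, side/2)``: the approximation
    planes and the summed-detail planes, with row i corresponding to image
    i of the input.
    """
    if isinstance(ds, Dataset):
        if len(ds) == 0:
            return (np.zeros((0, 0, 0), dtype=np.float32),) * 2
        sides = {im.pixels.shape for im in ds.items}
        if len(sides) > 1:
            raise ValueError(f"heterogeneous image sizes: {sorted(sides)}")
        pixels = ds.pixels_array()
    else:
        pixels = np.asarray(ds)
        if pixels.shape[0] == 0:
            return (np.zeros((0, 0, 0), dtype=np.float32),) * 2
    side = pixels.shape[1]
    if side % 2 or pixels.shape[1] != pixels.shape[2]:
        raise ValueError(f"images must be square with even side, got {pixels.shape[1:]}")
    _check_wavelet(wavelet_name)
    # pywt.dwt2 vectorises over leading axes
    a, (h, v, d) = pywt.dwt2(pixels.astype(np.float64), wavelet_name,
                             mode=_DWT_MODE, axes=(-2, -1))
    return a.astype(np.float32), (h + v + d).astype(np.float32)


def intensity_homogenization(pos_pixels: np.ndarray, neg_pixels: np.ndarray,
                             wavelet_name: str = DEFAULT_WAVELET
                             ) -> tuple[float, float]:
    """Quantify the homogenization the approximation plane performs.

    For a positive- and a negative-intensity image of the same cell, the
    low-pass plane suppresses the noise and amplitude-coded texture that
    distinguish the two fluorescence modes, so the two approximation
    planes resemble each other more than the raw images do.  Returns the
    Pearson correlation between the display-normalized (min-max scaled)
    raw images and between their approximation planes; homogenization
    shows as ``approx_similarity > raw_similarity``.
    """
    def norm(x):
        x = np.asarray(x, dtype=np.float64)
        rng_ = x.max() - x.min()
        return (x - x.min()) / (rng_ + 1e-12)

    raw = float(np.corrcoef(norm(pos_pixels).ravel(), norm(neg_pixels).ravel())[0, 1])
    a_p = dwt_decompose(np.asarray(pos_pixels), wavelet_name).A
    a_n = dwt_decompose(np.asarray(neg_pixels), wavelet_name).A
    approx = float(np.corrcoef(norm(a_p).ravel(), norm(a_n).ravel())[0, 1])
    return raw, approx


class WaveletFrontend(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer: images -> stacked (A, D) channels.

    ``transform`` maps an ``(n, side, side)`` image array to an
    ``(n, 2, side/2, side/2)`` array with channel 0 the approximation and
    channel 1 the summed details, ready to be split between the two
    network branches.
    """

    def __init__(self, wavelet: str = DEFAULT_WAVELET):
        self.wavelet = wavelet

    def fit(self, X, y=None):
        _check_wavelet(self.wavelet)
        return self

    def transform(self, X) -> np.ndarray:
        a, d = batch_decompose(np.asarray(X), self.wavelet)
        return np.stack([a, d], axis=1)
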