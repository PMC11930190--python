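"""Generalized two-dimensional correlation spectroscopy (synchronous maps).

The dynamic spectrum of a perturbation series is the deviation of each
spectrum from a reference (by default the series mean).  The synchronous
correlation map is ``(1/(m-1)) * S^T S`` for the m x p dynamic matrix S —
the sample covariance of intensities across the perturbation axis.  For
supervised image models a rank-1 per-sample map ``s s^T`` is provided,
using the global mean spectrum as the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from scipy import ndimage

from .synthetic_data import SpectrumSet

__all__ = [
    "DynamicSpectra",
    "SyncMap",
    "dynamic_spectra",
    "synchronous_map",
    "per_sample_map",
    "render_map",
    "sample_images",
]


@dataclass
class DynamicSpectra:
    """Deviations of m spectra from a reference, on a shared grid."""

    matrix: np.ndarray  # m x p
    reference: np.ndarray  # p
    wavenumbers: np.ndarray
    perturbation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.reference = np.asarray(self.reference, dtype=float)
        if self.matrix.shape[1] != self.reference.size:
            raise ValueError("dynamic matrix width must match reference length")

    @property
    def m(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SyncMap:
    """Symmetric synchronous correlation intensities for one band window."""

    matrix: np.ndarray  # p x p
    wavenumbers: np.ndarray
    m_used: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("synchronous map must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("synchronous map must be symmetric")


def dynamic_spectra(
    spectra: SpectrumSet, reference: np.ndarray | None = None
) -> DynamicSpectra:
    """Dynamic spectra: each row minus the reference (default: series mean)."""
    X = spectra.absorbance
    if reference is None:
        reference = X.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (spectra.n_points,):
        raise ValueError("reference grid length mismatch")
    return DynamicSpectra(X - reference, reference, spectra.wavenumbers)


def synchronous_map(dyn: DynamicSpectra) -> SyncMap:
    """Synchronous 2D correlation map ``(1/(m-1)) S^T S``."""
    if dyn.m < 2:
        raise ValueError("synchronous map needs m >= 2 spectra")
    S = dyn.matrix
    phi = (S.T @ S) / (dyn.m - 1)
    phi = 0.5 * (phi + phi.T)  # kill fp asymmetry
    return SyncMap(phi, dyn.wavenumbers, dyn.m)


def per_sample_map(
    spectrum: np.ndarray, reference: np.ndarray, wavenumbers: np.ndarray
) -> SyncMap:
    """Rank-1 outer-product map of one spectrum against a fixed reference.

    With ``s = spectrum - reference`` the map is ``s s^T`` (the m = 1 outer
    product, no 1/(m-1) factor); it is symmetric with rank at most 1.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if spectrum.shape != reference.shape:
        raise ValueError("spectrum/reference grid mismatch")
    s = spectrum - reference
    return SyncMap(np.outer(s, s), np.asarray(wavenumbers, dtype=float), 1)


def render_map(
    sync: SyncMap,
    window: tuple[float, float] | None = None,
    size: int = 224,
    cmap: str = "jet",
) -> np.ndarray:
    """Render a synchronous map as a ``size x size x 3`` uint8 raster.

    The requested wavenumber window is cut from the map, min-max normalized
    per image (a constant map becomes uniform mid-scale), resampled to the
    target size with bilinear interpolation, and colorized.  Deterministic
    for fixed inputs.
    """
    mat = sync.matrix
    if window is not None:
        lo, hi = min(window), max(window)
        mask = (sync.wavenumbers >= lo) & (sync.wavenumbers <= hi)
        if not mask.any():
            raise ValueError(f"window {window} cm^-1 is empty on this grid")
        mat = mat[np.ix_(mask, mask)]
    lo_v, hi_v = float(mat.min()), float(mat.max())
    if hi_v - lo_v < 1e-300:
        norm = np.full(mat.shape, 0.5)
    else:
        norm = (mat - lo_v) / (hi_v - lo_v)
    if norm.shape[0] != size:
        zoom = (size / norm.shape[0], size / norm.shape[1])
        norm = ndimage.zoom(norm, zoom, order=1, grid_mode=True, mode="nearest")
        norm = np.clip(norm, 0.0, 1.0)
    rgb = colormaps[cmap](norm)[..., :3]
    return (rgb * 255.0 + 0.5).astype(np.uint8)


def sample_images(
    spectra: SpectrumSet,
    size: int = 224,
    window: tuple[float, float] | None = None,
    cmap: str = "jet",
) -> np.ndarray:
    """Per-sample rank-1 map rasters for the whole set.

    Returns a float32 array of shape ``(n, size, size, 3)`` scaled to
    [0, 1]; the reference is the global mean spectrum of the set.
    """
    reference = spectra.absorbance.mean(axis=0)
    out = np.empty((spectra.n_samples, size, size, 3), dtype=np.float32)
    for i in range(spectra.n_samples):
        m = per_sample_map(spectra.absorbance[i], reference, spectra.wavenumbers)
        out[i] = render_map(m, window=window, size=size, cmap=cmap) / 255.0
    return out
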