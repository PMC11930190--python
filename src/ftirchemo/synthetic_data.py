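"""Synthetic FTIR spectrum and concentration-table generation.

Spectra are sums of Gaussian bands on a descending wavenumber grid with
class-dependent band intensities, multiplicative scatter (per-sample slope
and offset), a random low-order polynomial baseline and additive white
noise.  Concentration tables are generated as linear functionals of the
absorbance inside a fingerprint band so that downstream calibration models
have a known ground truth to recover.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` child streams (see :func:`_streams`), so each
generation step is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PeakDef",
    "ExperimentDesign",
    "SpectrumSet",
    "ConcentrationTable",
    "default_grid",
    "default_peaks",
    "default_compounds",
    "generate_spectra",
    "generate_concentrations",
]

#: Default temperature-class labels (degrees Celsius of the drying step).
DEFAULT_CLASS_LABELS = ("35C", "45C", "55C", "65C", "75C")

#: Default per-class sample counts for the discrimination design.
DEFAULT_CLASS_COUNTS = (22, 18, 18, 21, 20)

#: Fingerprint band used to couple concentrations to spectra (cm^-1).
FINGERPRINT_BAND = (1800.0, 1200.0)


@dataclass(frozen=True)
class PeakDef:
    """One Gaussian band of the synthetic spectrum library.

    Parameters
    ----------
    center : float
        Band position in cm^-1; must lie inside [400, 4000].
    width : float
        Gaussian sigma in cm^-1; strictly positive.
    base_amplitude : float
        Class-independent peak absorbance.
    class_deltas : tuple of float
        Additive per-class amplitude offsets; one entry per class.
    """

    center: float
    width: float
    base_amplitude: float
    class_deltas: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (400.0 <= self.center <= 4000.0):
            raise ValueError(f"peak center {self.center} outside [400, 4000] cm^-1")
        if self.width <= 0:
            raise ValueError("peak width must be > 0")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Unit-amplitude Gaussian profile evaluated on a grid."""
        return np.exp(-0.5 * ((wavenumbers - self.center) / self.width) ** 2)


@dataclass(frozen=True)
class ExperimentDesign:
    """Parameters of one synthetic acquisition campaign."""

    class_labels: tuple[str, ...] = DEFAULT_CLASS_LABELS
    samples_per_class: tuple[int, ...] = DEFAULT_CLASS_COUNTS
    grid_start: float = 4000.0
    grid_end: float = 400.0
    grid_step: float = 4.0
    scatter_slope_sd: float = 0.01
    scatter_offset_sd: float = 0.005
    baseline_coeffs_sd: tuple[float, ...] = (0.005, 0.002, 0.001)
    noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_labels) != len(self.samples_per_class):
            raise ValueError(
                "samples_per_class length must match class_labels length "
                f"({len(self.samples_per_class)} != {len(self.class_labels)})"
            )
        if any(c <= 0 for c in self.samples_per_class):
            raise ValueError("all class sample counts must be > 0")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_class))

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)


@dataclass
class SpectrumSet:
    """A wavenumber grid with an absorbance matrix and per-sample labels.

    The central exchange object of the pipeline: every preprocessing step
    consumes and produces one.  The grid is stored descending (FTIR
    convention); rows of ``absorbance`` are samples.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.labels = np.asarray(self.labels)
        self.sample_ids = np.asarray(self.sample_ids)
        d = np.diff(self.wavenumbers)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotonic")
        if self.absorbance.shape[1] != self.wavenumbers.size:
            raise ValueError("absorbance column count must equal grid length")
        if self.absorbance.shape[0] != self.labels.size:
            raise ValueError("absorbance row count must equal number of labels")
        if self.sample_ids.size != self.labels.size:
            raise ValueError("sample_ids length must equal number of labels")
        if len(set(self.sample_ids.tolist())) != self.sample_ids.size:
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    @property
    def grid_step(self) -> float:
        return float(abs(self.wavenumbers[1] - self.wavenumbers[0]))

    def band_mask(self, high: float, low: float) -> np.ndarray:
        """Boolean mask of grid points inside [low, high] cm^-1 (inclusive)."""
        lo, hi = min(low, high), max(low, high)
        return (self.wavenumbers >= lo) & (self.wavenumbers <= hi)

    def restrict(self, high: float, low: float) -> "SpectrumSet":
        """New set restricted to the [low, high] cm^-1 window."""
        mask = self.band_mask(high, low)
        if not mask.any():
            raise ValueError(f"band [{low}, {high}] cm^-1 contains no grid points")
        return self.replace(
            wavenumbers=self.wavenumbers[mask], absorbance=self.absorbance[:, mask]
        )

    def subset(self, indices: Sequence[int]) -> "SpectrumSet":
        idx = np.asarray(indices, dtype=int)
        return self.replace(
            absorbance=self.absorbance[idx],
            labels=self.labels[idx],
            sample_ids=self.sample_ids[idx],
        )

    def replace(self, **kwargs) -> "SpectrumSet":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ConcentrationTable:
    """Samples x compounds concentration matrix with taste annotations."""

    values: np.ndarray
    compound_names: tuple[str, ...]
    taste_classes: tuple[str, ...]
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids)
        if len(set(self.compound_names)) != len(self.compound_names):
            raise ValueError("compound names must be unique")
        if len(self.taste_classes) != len(self.compound_names):
            raise ValueError("taste_classes length must match compound_names")
        if self.values.shape != (self.sample_ids.size, len(self.compound_names)):
            raise ValueError("values shape inconsistent with ids/compounds")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.values.shape[1]

    def column(self, compound: str) -> np.ndarray:
        try:
            j = self.compound_names.index(compound)
        except ValueError:
            raise KeyError(f"unknown compound {compound!r}") from None
        return self.values[:, j]


def default_grid(design: ExperimentDesign | None = None) -> np.ndarray:
    """Descending arithmetic wavenumber grid.

    The default design spans 4000 down to 400 cm^-1 in 4 cm^-1 steps,
    i.e. 901 points.
    """
    design = design or ExperimentDesign()
    start, end, step = design.grid_start, design.grid_end, design.grid_step
    hi, lo = max(start, end), min(start, end)
    if step > hi - lo:
        raise ValueError("grid_step larger than the grid range")
    n = int(round((hi - lo) / step)) + 1
    return hi - step * np.arange(n)


def default_peaks(n_classes: int = 5) -> list[PeakDef]:
    """Band library at the named fingerprint positions.

    Broad O-H/N-H bands get sigma 20 cm^-1, sharp bands sigma 16 cm^-1
    (FWHM ~ 38 cm^-1; narrower bands disappear when correlation maps are
    rasterized to small training images).
    Class deltas are fixed (not drawn) so that class-mean spectra are
    deterministic; the patterns make every adjacent class pair differ at
    several bands by amounts large against the default noise floor.
    """
    broad = 20.0
    sharp = 16.0
    if n_classes != 5:
        return _generic_peaks(n_classes, broad, sharp)
    # (center, width, base amplitude, per-class deltas).  Each class gets
    # its discriminating intensity in a different band group (aliphatic /
    # amide / carboxylate / polysaccharide / low-wavenumber), so no class
    # deviation pattern is the negative of another: rank-1 correlation
    # maps are sign-blind and antipodal patterns would be inseparable.
    spec = [
        (3200.0, broad, 0.60, (0.00, 0.02, 0.04, 0.06, 0.08)),
        (2928.0, sharp, 0.35, (0.10, 0.01, 0.00, 0.00, 0.01)),
        (2840.0, sharp, 0.25, (0.08, 0.01, 0.00, 0.01, 0.00)),
        (1620.0, sharp, 0.55, (0.00, 0.10, 0.01, 0.00, 0.01)),
        (1554.0, sharp, 0.40, (0.01, 0.08, 0.00, 0.01, 0.00)),
        (1400.0, sharp, 0.35, (0.00, 0.01, 0.09, 0.00, 0.01)),
        (1228.0, sharp, 0.20, (0.01, 0.00, 0.07, 0.01, 0.00)),
        (1147.0, sharp, 0.30, (0.00, 0.01, 0.00, 0.07, 0.01)),
        (1100.0, sharp, 0.45, (0.01, 0.00, 0.01, 0.09, 0.00)),
        (1017.0, sharp, 0.70, (0.00, 0.01, 0.00, 0.08, 0.01)),
        (918.0, sharp, 0.25, (0.01, 0.00, 0.01, 0.00, 0.07)),
        (890.0, sharp, 0.15, (0.00, 0.01, 0.00, 0.01, 0.05)),
        (760.0, sharp, 0.12, (0.01, 0.00, 0.01, 0.00, 0.04)),
        (620.0, sharp, 0.20, (0.00, 0.01, 0.00, 0.01, 0.06)),
        (526.0, sharp, 0.18, (0.01, 0.00, 0.01, 0.00, 0.05)),
    ]
    return [PeakDef(c, w, a, d) for c, w, a, d in spec]


_CENTERS = (3200.0, 2928.0, 2840.0, 1620.0, 1554.0, 1400.0, 1228.0, 1147.0,
            1100.0, 1017.0, 918.0, 890.0, 760.0, 620.0, 526.0)
_BASE_AMPS = (0.60, 0.35, 0.25, 0.55, 0.40, 0.35, 0.20, 0.30,
              0.45, 0.70, 0.25, 0.15, 0.12, 0.20, 0.18)


def _generic_peaks(n_classes: int, broad: float, sharp: float) -> list[PeakDef]:
    """Peak library for a non-default class count.

    The broad 3200 band carries a monotone class trend; each sharp band is
    assigned one discriminating class round-robin, giving disjoint
    per-class signatures for any number of classes.
    """
    if n_classes < 1:
        raise ValueError("need at least one class")
    peaks = []
    trend = tuple(0.08 * k / max(n_classes - 1, 1) for k in range(n_classes))
    peaks.append(PeakDef(_CENTERS[0], broad, _BASE_AMPS[0], trend))
    for i, (c, a) in enumerate(zip(_CENTERS[1:], _BASE_AMPS[1:])):
        deltas = [0.0] * n_classes
        deltas[i % n_classes] = 0.08
        peaks.append(PeakDef(c, sharp, a, tuple(deltas)))
    return peaks


#: Eleven taste-active compounds used for the default concentration table.
DEFAULT_COMPOUNDS: tuple[tuple[str, str], ...] = (
    ("L-tyrosine", "bitter"),
    ("L-arginine", "bitter"),
    ("L-alanine", "sweet"),
    ("L-serine", "sweet"),
    ("L-methionine", "other"),
    ("adipic acid", "sour"),
    ("lactic acid", "sour"),
    ("tartaric acid", "sour"),
    ("creatine", "umami"),
    ("pantothenic acid", "other"),
    ("taurine", "other"),
)


def default_compounds() -> tuple[tuple[str, str], ...]:
    return DEFAULT_COMPOUNDS


def _streams(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Named child generators of one root seed.

    Streams are spawned in a fixed name order so that each consumer draws
    from its own generator regardless of how many draws the others make.
    """
    order = ("scatter", "baseline", "noise", "coupling", "conc_noise")
    children = np.random.SeedSequence(seed).spawn(len(order))
    by_name = {n: np.random.default_rng(s) for n, s in zip(order, children)}
    return {n: by_name[n] for n in names} if names else by_name


def generate_spectra(
    design: ExperimentDesign, peaks: Sequence[PeakDef] | None = None
) -> SpectrumSet:
    """Draw one synthetic spectrum per designed sample.

    For a sample of class k the absorbance is
    ``slope * sum_i (base_i + delta_i[k]) * G(v; center_i, width_i)
    + offset + baseline(v) + eps(v)`` with ``slope ~ 1 + N(0, slope_sd)``,
    ``offset ~ N(0, offset_sd)``, a per-sample random polynomial baseline
    and iid Gaussian noise.  Deterministic for a fixed design seed.
    """
    if peaks is None:
        peaks = default_peaks(design.n_classes)
    peaks = list(peaks)
    if not peaks:
        raise ValueError("peak list must be non-empty")
    for p in peaks:
        if len(p.class_deltas) != design.n_classes:
            raise ValueError(
                f"peak at {p.center} cm^-1 has {len(p.class_deltas)} class "
                f"deltas for {design.n_classes} classes"
            )

    grid = default_grid(design)
    n, p_pts = design.n_samples, grid.size
    rng = _streams(design.seed)

    profiles = np.stack([p.profile(grid) for p in peaks])  # n_peaks x p
    base = np.array([p.base_amplitude for p in peaks])
    deltas = np.array([p.class_deltas for p in peaks])  # n_peaks x n_classes

    class_idx = np.repeat(np.arange(design.n_classes), design.samples_per_class)
    clean = (base[:, None] + deltas[:, class_idx]).T @ profiles  # n x p

    slope = 1.0 + rng["scatter"].normal(0.0, design.scatter_slope_sd, size=(n, 1))
    offset = rng["scatter"].normal(0.0, design.scatter_offset_sd, size=(n, 1))

    # baseline: polynomial in a [-1, 1]-scaled grid coordinate, per sample
    u = np.linspace(-1.0, 1.0, p_pts)
    baseline = np.zeros((n, p_pts))
    for order, sd in enumerate(design.baseline_coeffs_sd):
        coeff = rng["baseline"].normal(0.0, sd, size=(n, 1))
        baseline += coeff * u**order

    eps = rng["noise"].normal(0.0, design.noise_sd, size=(n, p_pts))

    absorbance = slope * clean + offset + baseline + eps
    labels = np.repeat(np.array(design.class_labels), design.samples_per_class)
    width = len(str(n))
    sample_ids = np.array(
        [f"{lab}_{i:0{width}d}" for i, lab in enumerate(labels)]
    )
    return SpectrumSet(grid, absorbance, labels, sample_ids)


@dataclass
class GenerationLog:
    """Ground truth retained from :func:`generate_concentrations`."""

    coupling: np.ndarray  # n_compounds x n_band_points
    intercepts: np.ndarray
    band_mask: np.ndarray
    clipped: list[tuple[int, int]] = field(default_factory=list)


def generate_concentrations(
    spectra: SpectrumSet,
    coupling: np.ndarray | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
    compounds: Sequence[tuple[str, str]] | None = None,
    band: tuple[float, float] = FINGERPRINT_BAND,
) -> tuple[ConcentrationTable, GenerationLog]:
    """Concentrations as noisy linear functionals of the fingerprint band.

    ``concentration = w . x_band + intercept + N(0, noise_sd)``, clipped at
    zero (clipping events are recorded in the returned log).  The true
    coupling ``w`` and intercepts are returned for recovery tests.
    """
    compounds = tuple(compounds) if compounds is not None else DEFAULT_COMPOUNDS
    names = tuple(c for c, _ in compounds)
    tastes = tuple(t for _, t in compounds)
    mask = spectra.band_mask(*band)
    x_band = spectra.absorbance[:, mask]
    n_band = int(mask.sum())

    rng = _streams(seed)
    if coupling is None:
        # smooth sparse weights: a few Gaussian bumps inside the band
        v = spectra.wavenumbers[mask]
        coupling = np.zeros((len(names), n_band))
        for j in range(len(names)):
            n_bumps = int(rng["coupling"].integers(2, 5))
            centers = rng["coupling"].uniform(v.min(), v.max(), n_bumps)
            signs = rng["coupling"].choice([-1.0, 1.0], n_bumps)
            widths = rng["coupling"].uniform(15.0, 60.0, n_bumps)
            for c, s, w in zip(centers, signs, widths):
                coupling[j] += s * np.exp(-0.5 * ((v - c) / w) ** 2)
    else:
        coupling = np.atleast_2d(np.asarray(coupling, dtype=float))
        if coupling.shape[1] != n_band:
            raise ValueError(
                f"coupling has {coupling.shape[1]} weights but the "
                f"{band} cm^-1 band holds {n_band} grid points"
            )

    linear = x_band @ coupling.T  # n_samples x n_compounds
    # intercepts lift every compound comfortably above zero
    intercepts = 1.0 - linear.min(axis=0) + 0.5 * np.abs(linear).mean(axis=0)
    values = linear + intercepts
    if noise_sd > 0:
        values = values + rng["conc_noise"].normal(0.0, noise_sd, values.shape)

    log = GenerationLog(coupling=coupling, intercepts=intercepts, band_mask=mask)
    neg = np.argwhere(values < 0)
    for i, j in neg:
        log.clipped.append((int(i), int(j)))
    values = np.clip(values, 0.0, None)

    table = ConcentrationTable(values, names, tastes, spectra.sample_ids.copy())
    return table, log
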