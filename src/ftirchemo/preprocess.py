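"""Row-wise spectral pretreatments and named pretreatment chains.

All operations act per sample and never mix information across samples
except through an explicitly stored MSC reference, which must be learned on
calibration data and reused on held-out data.  Output grids always equal
input grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import savgol_filter

from .synthetic_data import SpectrumSet

__all__ = [
    "msc",
    "snv",
    "savitzky_golay",
    "PretreatmentChain",
    "apply_chain",
    "CHAIN_NAMES",
]

# Savitzky-Golay defaults (window / polyorder); the derivative steps use
# S-G differentiation rather than plain finite differences to keep noise
# amplification under control.
SG_SMOOTH = {"window": 15, "polyorder": 2, "deriv": 0}
SG_FIRST = {"window": 15, "polyorder": 2, "deriv": 1}
SG_SECOND = {"window": 15, "polyorder": 3, "deriv": 2}


def _msc_rows(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    ref = reference - reference.mean()
    denom = float(ref @ ref)
    if denom <= 0:
        raise ValueError("MSC reference has zero variance")
    Xc = X - X.mean(axis=1, keepdims=True)
    slopes = (Xc @ ref) / denom
    if np.any(slopes == 0):
        raise ValueError("MSC slope of zero; spectrum orthogonal to reference")
    intercepts = X.mean(axis=1) - slopes * reference.mean()
    return (X - intercepts[:, None]) / slopes[:, None]


def msc(
    spectra: SpectrumSet, reference: np.ndarray | None = None
) -> tuple[SpectrumSet, np.ndarray]:
    """Multiplicative scatter correction.

    Each spectrum ``x`` is regressed on the reference (least squares,
    ``x ~ a*ref + b``) and replaced by ``(x - b) / a``.  When no reference
    is supplied, the mean spectrum of the set is used and returned so it can
    be reapplied to held-out data.

    Returns the corrected set together with the reference used.
    """
    X = spectra.absorbance
    if reference is None:
        if X.shape[0] < 2:
            raise ValueError("internal-mean MSC needs at least 2 samples")
        reference = X.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (spectra.n_points,):
        raise ValueError("reference length must match the grid")
    return spectra.replace(absorbance=_msc_rows(X, reference)), reference


def snv(spectra: SpectrumSet) -> SpectrumSet:
    """Standard normal variate: each row to mean 0, sample sd 1 (ddof=1)."""
    X = spectra.absorbance
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        raise ValueError("SNV undefined for constant rows")
    out = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return spectra.replace(absorbance=out)


def savitzky_golay(
    spectra: SpectrumSet, window: int = 15, polyorder: int = 2, deriv: int = 0
) -> SpectrumSet:
    """Savitzky-Golay smoothing / differentiation along the wavenumber axis.

    Derivatives are scaled by the grid step, so a first derivative is in
    absorbance per cm^-1 with respect to the *wavenumber* axis even though
    the grid is stored descending.  Edges use a polynomial fit on the
    truncated window (scipy's ``mode='interp'``).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if deriv not in (0, 1, 2):
        raise ValueError("deriv must be 0, 1 or 2")
    if deriv > polyorder:
        raise ValueError("deriv must be <= polyorder")
    step = spectra.wavenumbers[1] - spectra.wavenumbers[0]
    out = savgol_filter(
        spectra.absorbance,
        window_length=window,
        polyorder=polyorder,
        deriv=deriv,
        delta=abs(step),
        axis=1,
        mode="interp",
    )
    if step < 0:  # descending grid: flip derivative sign per order
        out = out * (-1.0) ** deriv
    return spectra.replace(absorbance=out)


_SCATTER_STEPS = {"MSC", "SNV"}

#: CLI chain names accepted verbatim.
CHAIN_NAMES = (
    "Raw",
    "FD",
    "SD",
    "S-G",
    "MSC",
    "SNV",
    "FD+MSC",
    "FD+SNV",
    "SD+MSC",
    "SD+SNV",
)


@dataclass(frozen=True)
class PretreatmentChain:
    """An ordered list of pretreatment steps with per-step parameters.

    Steps are drawn from ``{"MSC", "SNV", "FD", "SD", "SG"}``; at most one
    scatter-correction step is allowed, derivative orders are fixed at 1
    (FD) and 2 (SD), and S-G windows must be odd and larger than the
    polynomial order.
    """

    steps: tuple[str, ...]
    params: tuple[frozenset, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        known = {"MSC", "SNV", "FD", "SD", "SG"}
        for s in self.steps:
            if s not in known:
                raise ValueError(f"unknown pretreatment step {s!r}")
        if sum(s in _SCATTER_STEPS for s in self.steps) > 1:
            raise ValueError("at most one scatter-correction step per chain")
        if not self.params:
            object.__setattr__(self, "params", tuple(frozenset() for _ in self.steps))
        if len(self.params) != len(self.steps):
            raise ValueError("params length must match steps length")
        if not self.name:
            object.__setattr__(self, "name", "+".join(self.steps) or "Raw")

    @classmethod
    def from_string(cls, name: str) -> "PretreatmentChain":
        """Parse a printed chain name such as ``"FD+MSC"`` or ``"Raw"``.

        The printed name is applied left to right: ``"FD+MSC"`` takes the
        first derivative and then scatter-corrects the derivative spectra.
        """
        label = name.strip()
        if label.lower() == "raw" or label == "":
            return cls(steps=(), name="Raw")
        alias = {"S-G": "SG", "SG": "SG", "FD": "FD", "SD": "SD",
                 "MSC": "MSC", "SNV": "SNV"}
        steps = []
        for part in label.split("+"):
            key = part.strip().upper().replace("S-G", "S-G")
            key = "S-G" if key in ("S-G", "SG") else key
            if key not in alias and key != "S-G":
                raise ValueError(f"unknown pretreatment {part.strip()!r}")
            steps.append(alias.get(key, "SG"))
        return cls(steps=tuple(steps), name=label)


def _step_params(step: str, overrides: frozenset) -> dict[str, Any]:
    base = {"FD": SG_FIRST, "SD": SG_SECOND, "SG": SG_SMOOTH}.get(step, {})
    out = dict(base)
    out.update(dict(overrides))
    return out


@dataclass
class ChainState:
    """Fitted state of a stateful chain (currently only the MSC reference)."""

    msc_reference: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def apply_chain(
    spectra: SpectrumSet,
    chain: PretreatmentChain,
    fitted_state: ChainState | None = None,
) -> tuple[SpectrumSet, ChainState]:
    """Apply a pretreatment chain strictly in listed order.

    When ``fitted_state`` is None the chain is *fit*: the MSC reference (if
    any) is learned from this data and returned for reuse.  When a state is
    given, its reference is applied unchanged, so held-out data is
    corrected against the calibration-derived reference.
    """
    fitting = fitted_state is None
    state = ChainState() if fitting else fitted_state
    out = spectra
    for step, overrides in zip(chain.steps, chain.params):
        if step == "MSC":
            if fitting:
                out, ref = msc(out)
                state.msc_reference = ref
            else:
                if state.msc_reference is None:
                    raise ValueError(
                        "chain contains MSC but fitted_state carries no reference"
                    )
                out, _ = msc(out, reference=state.msc_reference)
        elif step == "SNV":
            out = snv(out)
        else:  # FD / SD / SG
            out = savitzky_golay(out, **_step_params(step, overrides))
    return out, state
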