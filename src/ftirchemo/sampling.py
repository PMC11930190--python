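"""Deterministic Kennard-Stone sample-set partitioning.

The Kennard-Stone order starts from the most distant pair of samples and
greedily adds the sample whose minimum Euclidean distance to the selected
set is largest.  All ties break toward the lowest index, making the order
a pure function of the feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["SplitIndices", "kennard_stone_order", "split"]


@dataclass
class SplitIndices:
    """Named, disjoint index partitions covering all samples."""

    partitions: dict[str, np.ndarray]
    fractions: dict[str, float]
    feature_space: str = "raw"

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, idx in self.partitions.items():
            idx = np.asarray(idx, dtype=int)
            self.partitions[name] = idx
            if idx.size == 0:
                raise ValueError(f"partition {name!r} is empty")
            overlap = seen.intersection(idx.tolist())
            if overlap:
                raise ValueError(f"partitions overlap at indices {sorted(overlap)}")
            seen.update(idx.tolist())
        self._n = len(seen)

    @property
    def n_samples(self) -> int:
        return self._n

    def __getitem__(self, name: str) -> np.ndarray:
        return self.partitions[name]


def kennard_stone_order(features: np.ndarray) -> np.ndarray:
    """Total Kennard-Stone ordering of all samples.

    The first two entries are the maximally distant pair (ties by the
    lexicographically lowest index pair); every later entry maximizes its
    minimum distance to the already selected set (ties by lowest index).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("Kennard-Stone needs at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain missing/non-finite values")

    D = squareform(pdist(X))
    # seed pair: max distance, lexicographic lowest (i, j) on ties
    iu = np.triu_indices(n, k=1)
    dists = D[iu]
    best = dists.max()
    tie = np.flatnonzero(dists == best)
    # triu_indices enumerates (0,1), (0,2), ... so the first tie already is
    # the lexicographically smallest pair
    i0, j0 = int(iu[0][tie[0]]), int(iu[1][tie[0]])

    order = [i0, j0]
    selected = np.zeros(n, dtype=bool)
    selected[[i0, j0]] = True
    min_d = np.minimum(D[i0], D[j0])
    min_d[selected] = -np.inf
    for _ in range(n - 2):
        nxt = int(np.argmax(min_d))  # argmax returns lowest index on ties
        order.append(nxt)
        selected[nxt] = True
        min_d = np.minimum(min_d, D[nxt])
        min_d[selected] = -np.inf
    return np.array(order, dtype=int)


def _largest_remainder(n: int, fracs: list[float]) -> list[int]:
    quotas = [f * n for f in fracs]
    sizes = [int(np.floor(q)) for q in quotas]
    short = n - sum(sizes)
    remainders = sorted(
        range(len(fracs)), key=lambda k: (-(quotas[k] - sizes[k]), k)
    )
    for k in remainders[:short]:
        sizes[k] += 1
    return sizes


def split(
    features: np.ndarray,
    fractions: dict[str, float],
    feature_space: str = "raw",
) -> SplitIndices:
    """Partition samples along the Kennard-Stone order.

    The first named partition takes the head of the K-S order; later
    partitions take the following blocks.  Partition sizes come from
    largest-remainder rounding of ``fraction * n`` so counts differ from the
    exact proportions by at most one.
    """
    names = list(fractions)
    fracs = [float(fractions[k]) for k in names]
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fracs)}")
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    sizes = _largest_remainder(n, fracs)
    if any(s == 0 for s in sizes):
        raise ValueError(f"a partition rounds to zero samples: {dict(zip(names, sizes))}")
    order = kennard_stone_order(X)
    parts: dict[str, np.ndarray] = {}
    at = 0
    for name, size in zip(names, sizes):
        parts[name] = np.sort(order[at : at + size])
        at += size
    return SplitIndices(parts, dict(zip(names, fracs)), feature_space)
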