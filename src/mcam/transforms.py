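"""Row-wise data transformations and distance metrics for the parameter grid.

Each transform operates on the dynamic measurement vector of a single
phosphopeptide (a row of the dataset), never across peptides. A transform
that produces a non-finite value for some row (log of a non-positive number,
zero variance under zscore, ...) marks the whole configuration *degenerate*
for that dataset; the clustering engine skips such configurations while still
counting them in the combinatorial grid.

Transform vocabulary: raw, center, zscore, normMax, rangeScale, log10, pow,
pareto, FFT, diff, normMax_log10, zscore_log10 (composites chain
left-to-right). Distance vocabulary: euclidean (optionally squared),
correlation (1 - Pearson r), cityblock, cosine, chebychev.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import distance as _sdist

TRANSFORM_NAMES = (
    "raw",
    "center",
    "zscore",
    "normMax",
    "rangeScale",
    "log10",
    "pow",
    "pareto",
    "FFT",
    "diff",
    "normMax_log10",
    "zscore_log10",
)

DISTANCE_NAMES = ("euclidean", "correlation", "cityblock", "cosine", "chebychev")


class DegenerateTransform(ValueError):
    """A transform produced a non-finite output for some row."""


@dataclass(frozen=True)
class TransformSpec:
    name: str

    def __post_init__(self) -> None:
        if self.name not in TRANSFORM_NAMES:
            raise ValueError(f"unknown transform: {self.name!r}")


@dataclass(frozen=True)
class DistanceSpec:
    name: str
    squared: bool = False  # Kmeans uses squared Euclidean

    def __post_init__(self) -> None:
        if self.name not in DISTANCE_NAMES:
            raise ValueError(f"unknown distance: {self.name!r}")


def _primitive(x: np.ndarray, name: str) -> np.ndarray:
    if name == "raw":
        return x
    if name == "center":
        return x - x.mean()
    if name == "zscore":
        s = x.std(ddof=1)
        if s == 0:
            raise DegenerateTransform("zscore of constant vector")
        return (x - x.mean()) / s
    if name == "normMax":
        m = x.max()
        if m == 0:
            raise DegenerateTransform("normMax with max 0")
        return x / m
    if name == "rangeScale":
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise DegenerateTransform("rangeScale of constant vector")
        return (x - lo) / (hi - lo)
    if name == "log10":
        if np.any(x <= 0):
            raise DegenerateTransform("log10 of non-positive value")
        return np.log10(x)
    if name == "pow":
        if np.any(x < 0):
            raise DegenerateTransform("pow (sqrt) of negative value")
        return np.sqrt(x)
    if name == "pareto":
        s = x.std(ddof=1)
        if s == 0:
            raise DegenerateTransform("pareto of constant vector")
        return (x - x.mean()) / np.sqrt(s)
    if name == "FFT":
        # magnitude spectrum of the full-length DFT; phase discarded, DC kept
        return np.abs(np.fft.fft(x))
    if name == "diff":
        return np.diff(x)
    raise ValueError(name)  # pragma: no cover


def apply_transform(row, spec: TransformSpec | str) -> np.ndarray:
    """Apply a (possibly composite) transform to one measurement vector.

    Composite names chain left-to-right: normMax_log10 is normMax then log10.
    Raises :class:`DegenerateTransform` where the math breaks down.
    """
    name = spec.name if isinstance(spec, TransformSpec) else TransformSpec(spec).name
    x = np.asarray(row, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DegenerateTransform("non-finite input")
    if name in ("normMax_log10", "zscore_log10"):
        parts = name.split("_")
    else:
        parts = [name]
    for part in parts:
        x = _primitive(x, part)
    if not np.all(np.isfinite(x)):
        raise DegenerateTransform(f"non-finite output of {name}")
    return x


def transform_matrix(values: np.ndarray, spec: TransformSpec | str) -> np.ndarray:
    """Apply a transform to every row of a matrix (fails on any degenerate row)."""
    return np.vstack([apply_transform(r, spec) for r in np.asarray(values, dtype=float)])


def distance(a, b, spec: DistanceSpec | str) -> float:
    """Distance between two equal-length vectors under *spec*."""
    if isinstance(spec, str):
        spec = DistanceSpec(spec)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    name = spec.name
    if name == "euclidean":
        d = _sdist.euclidean(a, b)
        return d * d if spec.squared else d
    if name == "cityblock":
        return _sdist.cityblock(a, b)
    if name == "chebychev":
        return _sdist.chebyshev(a, b)
    if name in ("correlation", "cosine"):
        if a.size < 2:
            raise ValueError(f"{name} distance needs vectors of length >= 2")
        if name == "correlation":
            if a.std() == 0 or b.std() == 0:
                raise ValueError("correlation distance undefined for constant vector")
            return float(_sdist.correlation(a, b))
        if not a.any() or not b.any():
            raise ValueError("cosine distance undefined for zero vector")
        return float(_sdist.cosine(a, b))
    raise ValueError(name)  # pragma: no cover


def pairwise_distances(X: np.ndarray, spec: DistanceSpec | str) -> np.ndarray:
    """Symmetric pairwise distance matrix over the rows of X."""
    if isinstance(spec, str):
        spec = DistanceSpec(spec)
    X = np.asarray(X, dtype=float)
    metric = {"chebychev": "chebyshev"}.get(spec.name, spec.name)
    if spec.name in ("correlation", "cosine"):
        norms = X.std(axis=1) if spec.name == "correlation" else np.abs(X).sum(axis=1)
        if np.any(norms == 0):
            raise ValueError(f"{spec.name} distance undefined for some row")
    D = _sdist.squareform(_sdist.pdist(X, metric=metric))
    if spec.name == "euclidean" and spec.squared:
        D = D**2
    # guard tiny negative round-off from pdist's correlation/cosine paths
    np.clip(D, 0.0, None, out=D)
    return D
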