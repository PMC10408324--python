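"""Input feature construction and z-score normalization.

Nine feature sets are supported, mirroring the candidate inputs of the
diagnostic network: single-ear HTLs or age-corrected HTLs (6 features),
one-ear HTLs combined with the age-associated hearing loss values
(12 features), both-ear HTLs or ACHTLs (12 features), and the full
18-feature set of both-ear HTLs plus AAHLs.

Canonical ordering is always right ear 1,2,3,4,6,8 kHz, then left ear, then
AAHL, restricted to the blocks present in the spec.  Normalization is a
training-set z-score: the per-feature mean is subtracted and the result is
divided by the per-feature population standard deviation; the statistics
fitted on the training cohorts are frozen and reused unchanged on any
evaluation data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .audiograms import FREQUENCIES_KHZ, AAHLTable, Individual

# block identifiers: which 6-dim blocks a feature set stacks, in order
_SPEC_BLOCKS: dict[str, tuple[str, ...]] = {
    "HTL-right": ("htl_right",),
    "HTL-left": ("htl_left",),
    "ACHTL-right": ("achtl_right",),
    "ACHTL-left": ("achtl_left",),
    "HTL-right+AAHL": ("htl_right", "aahl"),
    "HTL-left+AAHL": ("htl_left", "aahl"),
    "HTL-right+HTL-left": ("htl_right", "htl_left"),
    "ACHTL-right+ACHTL-left": ("achtl_right", "achtl_left"),
    "AAHL+HTL-right+HTL-left": ("htl_right", "htl_left", "aahl"),
}

#: Names of the nine supported feature sets.
FEATURE_SET_NAMES: tuple[str, ...] = tuple(_SPEC_BLOCKS)


@dataclass(frozen=True)
class FeatureSpec:
    """One of the nine named feature sets."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in _SPEC_BLOCKS:
            raise ValueError(
                f"unknown feature set {self.name!r}; expected one of {FEATURE_SET_NAMES}"
            )

    @property
    def blocks(self) -> tuple[str, ...]:
        return _SPEC_BLOCKS[self.name]

    @property
    def dimension(self) -> int:
        return 6 * len(self.blocks)

    @property
    def feature_names(self) -> list[str]:
        labels = {
            "htl_right": "HTL right",
            "htl_left": "HTL left",
            "achtl_right": "ACHTL right",
            "achtl_left": "ACHTL left",
            "aahl": "AAHL",
        }
        return [
            f"{labels[b]} {f} kHz" for b in self.blocks for f in FREQUENCIES_KHZ
        ]


@dataclass(frozen=True)
class NormalizationStats:
    """Frozen per-feature means and population SDs of a training set."""

    means: np.ndarray
    sds: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        if means.shape != sds.shape or means.ndim != 1:
            raise ValueError("means and sds must be 1-D vectors of equal length")
        if np.any(sds <= 0) or not np.all(np.isfinite(sds)) or not np.all(
            np.isfinite(means)
        ):
            raise ValueError("sds must be strictly positive and all stats finite")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        self.means.setflags(write=False)
        self.sds.setflags(write=False)

    @property
    def dimension(self) -> int:
        return len(self.means)


@dataclass(frozen=True)
class FeatureVector:
    """An ordered feature vector with its spec and normalization state."""

    values: np.ndarray
    spec: FeatureSpec
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.spec.dimension,):
            raise ValueError(
                f"{self.spec.name} expects {self.spec.dimension} values, "
                f"got shape {values.shape}"
            )
        object.__setattr__(self, "values", values)
        self.values.setflags(write=False)


def _block_values(ind: Individual, block: str, table: AAHLTable) -> np.ndarray:
    if block == "htl_right":
        return ind.right.as_vector()
    if block == "htl_left":
        return ind.left.as_vector()
    if block == "aahl":
        return table.lookup_all(ind.age)
    if block == "achtl_right":
        return ind.right.as_vector() - table.lookup_all(ind.age)
    if block == "achtl_left":
        return ind.left.as_vector() - table.lookup_all(ind.age)
    raise AssertionError(f"unknown block {block!r}")


def build_features(
    ind: Individual, spec: FeatureSpec, table: AAHLTable
) -> FeatureVector:
    """Un-normalized feature vector for one individual, canonical ordering."""
    values = np.concatenate([_block_values(ind, b, table) for b in spec.blocks])
    return FeatureVector(values, spec, normalized=False)


def build_feature_matrix(
    individuals: Iterable[Individual], spec: FeatureSpec, table: AAHLTable
) -> np.ndarray:
    """Stack un-normalized feature vectors into an ``(n, d)`` matrix."""
    return np.array(
        [build_features(ind, spec, table).values for ind in individuals], dtype=float
    )


def fit_normalization(
    individuals: Sequence[Individual], spec: FeatureSpec, table: AAHLTable
) -> NormalizationStats:
    """Per-feature mean and population SD over all training individuals.

    Exposed and control individuals are pooled; the SD divides by n
    (population convention).  A feature constant across the set has zero SD
    and is rejected.
    """
    if len(individuals) < 2:
        raise ValueError("normalization needs at least 2 individuals")
    X = build_feature_matrix(individuals, spec, table)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    if np.any(sds <= 0):
        bad = [spec.feature_names[i] for i in np.flatnonzero(sds <= 0)]
        raise ValueError(f"degenerate (constant) feature(s) in training set: {bad}")
    return NormalizationStats(means, sds, source=f"fitted on {len(individuals)} individuals")


def normalize(v: FeatureVector, stats: NormalizationStats) -> FeatureVector:
    """Apply frozen z-score stats: (value - mean) / sd, coordinate-wise."""
    if v.normalized:
        raise ValueError("feature vector is already normalized")
    if stats.dimension != v.spec.dimension:
        raise ValueError(
            f"stats dimension {stats.dimension} != feature dimension {v.spec.dimension}"
        )
    return FeatureVector((v.values - stats.means) / stats.sds, v.spec, normalized=True)


def denormalize(v: FeatureVector, stats: NormalizationStats) -> FeatureVector:
    """Inverse of :func:`normalize`."""
    if not v.normalized:
        raise ValueError("feature vector is not normalized")
    if stats.dimension != v.spec.dimension:
        raise ValueError("dimension mismatch")
    return FeatureVector(v.values * stats.sds + stats.means, v.spec, normalized=False)


def normalize_matrix(X: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Vectorized z-score for an ``(n, d)`` matrix of raw features."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != stats.dimension:
        raise ValueError("dimension mismatch")
    return (X - stats.means) / stats.sds
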