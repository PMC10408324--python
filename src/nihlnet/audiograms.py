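"""Domain types for pure-tone audiograms and cohorts of claimants/controls.

The diagnostic unit is an :class:`Individual`: an age in years plus one
:class:`Audiogram` per ear, each holding hearing threshold levels (HTLs, in
dB HL) at the six frequencies used for noise-induced hearing loss
assessment: 1, 2, 3, 4, 6 and 8 kHz.

Age-associated hearing loss (AAHL) is the HTL elevation expected from age
alone, tabulated by age and frequency in an :class:`AAHLTable`.  Subtracting
it from a measured HTL yields the age-corrected HTL (ACHTL), the residual
attributable to noise exposure.

Cohorts are read from and written to a fixed CSV dialect with columns
``id,age,r1,r2,r3,r4,r6,r8,l1,l2,l3,l4,l6,l8[,group]`` where ``r``/``l``
prefix the right/left ear and the digit is the frequency in kHz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: The six diagnostic frequencies, in kHz.
FREQUENCIES_KHZ: tuple[int, ...] = (1, 2, 3, 4, 6, 8)

#: Admissible HTL range of a clinical audiometer, dB HL.
HTL_MIN: float = -10.0
HTL_MAX: float = 130.0

#: Age range the types admit; ages outside the range typical of the
#: claimant populations (29-60 y) are accepted with a warning.
AGE_MIN, AGE_MAX = 18, 100
TYPICAL_AGE_RANGE = (29, 60)

_COHORT_COLUMNS = (
    ["id", "age"]
    + [f"r{f}" for f in FREQUENCIES_KHZ]
    + [f"l{f}" for f in FREQUENCIES_KHZ]
)

GroupLabel = Literal["exposed", "control"]


class CohortFormatError(ValueError):
    """A cohort or AAHL file does not conform to the expected dialect."""


class AudiogramValidationError(ValueError):
    """A parsed value violates a domain invariant (range, uniqueness...)."""


class AtypicalAgeWarning(UserWarning):
    """Age is admissible but outside the typical claimant range 29-60 y."""


@dataclass(frozen=True)
class Audiogram:
    """HTLs (dB HL) at the six diagnostic frequencies for one ear."""

    htl: Mapping[int, float]

    def __post_init__(self) -> None:
        freqs = tuple(sorted(self.htl))
        if freqs != FREQUENCIES_KHZ:
            raise AudiogramValidationError(
                f"audiogram must cover exactly {FREQUENCIES_KHZ} kHz, got {freqs}"
            )
        for f, v in self.htl.items():
            if not np.isfinite(v) or not (HTL_MIN <= v <= HTL_MAX):
                raise AudiogramValidationError(
                    f"HTL at {f} kHz is {v} dB HL, outside [{HTL_MIN}, {HTL_MAX}]"
                )
        object.__setattr__(self, "htl", dict(self.htl))

    def as_vector(self) -> np.ndarray:
        """HTLs in canonical frequency order (1, 2, 3, 4, 6, 8 kHz)."""
        return np.array([self.htl[f] for f in FREQUENCIES_KHZ], dtype=float)


@dataclass(frozen=True)
class Individual:
    """One person: age plus left/right audiograms; the unit of diagnosis."""

    id: str
    age: int
    left: Audiogram
    right: Audiogram
    group: Optional[GroupLabel] = None

    def __post_init__(self) -> None:
        if not (AGE_MIN <= self.age <= AGE_MAX):
            raise AudiogramValidationError(
                f"individual {self.id!r}: age {self.age} outside [{AGE_MIN}, {AGE_MAX}]"
            )
        lo, hi = TYPICAL_AGE_RANGE
        if not (lo <= self.age <= hi):
            warnings.warn(
                f"individual {self.id!r}: age {self.age} outside the typical "
                f"claimant range {lo}-{hi} y",
                AtypicalAgeWarning,
                stacklevel=2,
            )
        if self.group is not None and self.group not in ("exposed", "control"):
            raise AudiogramValidationError(
                f"individual {self.id!r}: group must be 'exposed' or 'control', "
                f"got {self.group!r}"
            )

    def ear(self, side: Literal["left", "right"]) -> Audiogram:
        if side not in ("left", "right"):
            raise ValueError(f"ear must be 'left' or 'right', got {side!r}")
        return self.left if side == "left" else self.right


@dataclass
class Cohort:
    """An ordered collection of individuals with unique ids."""

    individuals: list[Individual]
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ind in self.individuals:
            if ind.id in seen:
                raise AudiogramValidationError(
                    f"cohort {self.name!r}: duplicated id {ind.id!r}"
                )
            seen.add(ind.id)

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]


class AAHLTable:
    """Age-by-frequency table of expected age-associated hearing loss.

    Parameters
    ----------
    ages
        Tabulated ages (years), strictly increasing.
    values
        Array of shape ``(len(ages), 6)`` with the expected hearing loss in
        dB at the six diagnostic frequencies, in canonical order.  Values
        must be non-decreasing in age at every frequency.
    interpolation
        ``"linear"`` (linear-in-age between tabulated ages, the default) or
        ``"nearest"`` (nearest tabulated age; ties resolve to the younger).
    """

    def __init__(
        self,
        ages: Sequence[float],
        values: np.ndarray,
        interpolation: Literal["linear", "nearest"] = "linear",
    ) -> None:
        ages_arr = np.asarray(ages, dtype=float)
        vals = np.asarray(values, dtype=float)
        if ages_arr.ndim != 1 or len(ages_arr) < 1:
            raise CohortFormatError("AAHL table needs at least one age row")
        if np.any(np.diff(ages_arr) <= 0):
            raise CohortFormatError("AAHL table ages must be strictly increasing")
        if vals.shape != (len(ages_arr), len(FREQUENCIES_KHZ)):
            raise CohortFormatError(
                f"AAHL values must have shape ({len(ages_arr)}, 6), got {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise CohortFormatError("AAHL table contains non-finite values")
        if np.any(np.diff(vals, axis=0) < 0):
            raise CohortFormatError(
                "AAHL values must be non-decreasing in age at every frequency"
            )
        if interpolation not in ("linear", "nearest"):
            raise ValueError(f"unknown interpolation rule {interpolation!r}")
        self.ages = ages_arr
        self.values = vals
        self.interpolation = interpolation

    @property
    def age_range(self) -> tuple[float, float]:
        return float(self.ages[0]), float(self.ages[-1])

    def lookup(self, age: float, freq: int) -> float:
        """Expected age-associated hearing loss (dB) at ``age`` years, ``freq`` kHz."""
        if freq not in FREQUENCIES_KHZ:
            raise ValueError(f"frequency must be one of {FREQUENCIES_KHZ} kHz, got {freq}")
        lo, hi = self.age_range
        if not (lo <= age <= hi):
            raise AudiogramValidationError(
                f"age {age} outside AAHL table coverage [{lo}, {hi}]"
            )
        col = self.values[:, FREQUENCIES_KHZ.index(freq)]
        if self.interpolation == "nearest":
            # ties between brackets resolve to the younger age
            idx = int(np.argmin(np.abs(self.ages - age)))
            return float(col[idx])
        return float(np.interp(age, self.ages, col))

    def lookup_all(self, age: float) -> np.ndarray:
        """AAHL at all six frequencies, canonical order."""
        return np.array([self.lookup(age, f) for f in FREQUENCIES_KHZ])


def lookup_aahl(table: AAHLTable, age: float, freq: int) -> float:
    """Functional alias for :meth:`AAHLTable.lookup`."""
    return table.lookup(age, freq)


def age_corrected_htl(
    ind: Individual, ear: Literal["left", "right"], table: AAHLTable
) -> dict[int, float]:
    """Age-corrected HTLs: ACHTL(f) = HTL(f) - AAHL(age, f); may be negative."""
    audiogram = ind.ear(ear)
    return {f: audiogram.htl[f] - table.lookup(ind.age, f) for f in FREQUENCIES_KHZ}


# ---------------------------------------------------------------------------
# Delimited-text I/O


def read_cohort(path: str | Path, name: Optional[str] = None) -> Cohort:
    """Read a cohort CSV (dialect in the module docstring).

    Malformed rows are collected and reported together with their 1-based
    data-row numbers; any malformed row aborts the read.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"id": str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # pandas raises various parse errors
        raise CohortFormatError(f"{path}: cannot parse CSV: {exc}") from exc

    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing required column(s) {missing}")
    has_group = "group" in df.columns

    individuals: list[Individual] = []
    errors: list[str] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()
        try:
            group = None
            if has_group and not pd.isna(rec["group"]):
                group = str(rec["group"])
            ind = Individual(
                id=str(rec["id"]),
                age=int(rec["age"]),
                right=Audiogram({f: float(rec[f"r{f}"]) for f in FREQUENCIES_KHZ}),
                left=Audiogram({f: float(rec[f"l{f}"]) for f in FREQUENCIES_KHZ}),
                group=group,  # type: ignore[arg-type]
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {row_no}: {exc}")
            continue
        individuals.append(ind)
    if errors:
        raise AudiogramValidationError(
            f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors)
        )
    return Cohort(individuals, name=name if name is not None else path.stem)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV; ``read_cohort`` round-trips it field-for-field."""
    rows = []
    any_group = any(ind.group is not None for ind in cohort)
    for ind in cohort:
        rec: dict[str, object] = {"id": ind.id, "age": ind.age}
        for f in FREQUENCIES_KHZ:
            rec[f"r{f}"] = ind.right.htl[f]
        for f in FREQUENCIES_KHZ:
            rec[f"l{f}"] = ind.left.htl[f]
        if any_group:
            rec["group"] = ind.group if ind.group is not None else ""
        rows.append(rec)
    columns = _COHORT_COLUMNS + (["group"] if any_group else [])
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def load_aahl_table(
    path: str | Path, interpolation: Literal["linear", "nearest"] = "linear"
) -> AAHLTable:
    """Load an AAHL table from CSV with columns ``age,f1,f2,f3,f4,f6,f8``."""
    df = pd.read_csv(path)
    required = ["age"] + [f"f{f}" for f in FREQUENCIES_KHZ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing required column(s) {missing}")
    return AAHLTable(
        df["age"].to_numpy(float),
        df[[f"f{f}" for f in FREQUENCIES_KHZ]].to_numpy(float),
        interpolation=interpolation,
    )


def default_aahl_table(
    interpolation: Literal["linear", "nearest"] = "linear",
) -> AAHLTable:
    """The packaged default AAHL table.

    A synthetic stand-in with plausible male-median age-associated hearing
    loss values (quadratic growth in age above 18 y, steeper at high
    frequencies).  It is NOT the tabulation used by any specific published
    diagnostic method; analyses that must match a particular normative
    standard should load their own table with :func:`load_aahl_table`.
    """
    with resources.files("nihlnet.data").joinpath("aahl_default_synthetic.csv").open() as fh:
        df = pd.read_csv(fh)
    return AAHLTable(
        df["age"].to_numpy(float),
        df[[f"f{f}" for f in FREQUENCIES_KHZ]].to_numpy(float),
        interpolation=interpolation,
    )
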