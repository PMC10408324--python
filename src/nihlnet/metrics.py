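"""Diagnostic-performance mathematics.

Sensitivity, specificity and accuracy from confusion counts; the
signal-detection detectability index d' = z(sensitivity) - z(1 - specificity)
with z the standard-normal quantile; and the positive predictive value

    PPV = (sens * prev) / [(sens * prev) + ((1 - spec) * (1 - prev))]

as a function of the prevalence of the condition among the claimant
population.  ``PUBLISHED_METHODS`` holds the test-set operating points of
the three diagnostic methods compared in the source study; the internal
decision rules of the two audiogram-rule comparators are defined elsewhere
and enter only as (sensitivity, specificity) constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy.stats import norm

#: Published operating points (sensitivity, specificity) on the held-out
#: claimant/control test databases, per diagnostic method.
PUBLISHED_METHODS: dict[str, tuple[float, float]] = {
    "M-NIHL (2020)": (0.993, 0.402),
    "rM-NIHL": (0.976, 0.639),
    "MLP(18)": (0.986, 0.902),
}

#: Prevalence values used in the published PPV comparison.
PUBLISHED_PREVALENCES: tuple[float, ...] = (0.9, 0.5, 0.25)


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Confusion counts with derived proportions.

    ``sensitivity`` (``specificity``) is ``None`` — explicitly undefined,
    not zero — when the evaluation set contains no truly exposed (control)
    individuals.
    """

    true_positives: int
    false_negatives: int
    true_negatives: int
    false_positives: int

    def __post_init__(self) -> None:
        for name in ("true_positives", "false_negatives", "true_negatives", "false_positives"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_exposed(self) -> int:
        return self.true_positives + self.false_negatives

    @property
    def n_control(self) -> int:
        return self.true_negatives + self.false_positives

    @property
    def sensitivity(self) -> Optional[float]:
        if self.n_exposed == 0:
            return None
        return self.true_positives / self.n_exposed

    @property
    def specificity(self) -> Optional[float]:
        if self.n_control == 0:
            return None
        return self.true_negatives / self.n_control

    @property
    def accuracy(self) -> Optional[float]:
        n = self.n_exposed + self.n_control
        if n == 0:
            return None
        return (self.true_positives + self.true_negatives) / n

    @property
    def d_prime(self) -> Optional[float]:
        if self.sensitivity is None or self.specificity is None:
            return None
        return d_prime(self.sensitivity, self.specificity)


def performance(
    predictions: Sequence[bool], truth: Sequence[str]
) -> DiagnosticPerformance:
    """Confusion counts from per-individual predictions and true groups.

    ``predictions`` are booleans (True = positive diagnosis); ``truth``
    holds group labels ``"exposed"`` / ``"control"``.
    """
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have equal length")
    tp = fn = tn = fp = 0
    for pred, t in zip(predictions, truth):
        if t == "exposed":
            tp, fn = (tp + 1, fn) if pred else (tp, fn + 1)
        elif t == "control":
            fp, tn = (fp + 1, tn) if pred else (fp, tn + 1)
        else:
            raise ValueError(f"truth labels must be 'exposed'/'control', got {t!r}")
    return DiagnosticPerformance(tp, fn, tn, fp)


def d_prime(
    sensitivity: float,
    specificity: float,
    clamp_n: Optional[int] = None,
) -> float:
    """Detectability index d' = z(sensitivity) - z(1 - specificity).

    Both proportions must lie strictly in (0, 1) unless ``clamp_n`` is
    given, in which case proportions of exactly 0 or 1 are clamped to
    ``1/(2 clamp_n)`` / ``1 - 1/(2 clamp_n)`` (the standard correction for
    a sample of size ``clamp_n``).  Symmetric in its two arguments.
    """
    s, c = float(sensitivity), float(specificity)
    for v in (s, c):
        if not (0.0 <= v <= 1.0):
            raise ValueError("proportions must lie in [0, 1]")
    if clamp_n is not None:
        if clamp_n < 1:
            raise ValueError("clamp_n must be a positive sample size")
        lo, hi = 1.0 / (2 * clamp_n), 1.0 - 1.0 / (2 * clamp_n)
        s, c = min(max(s, lo), hi), min(max(c, lo), hi)
    if s in (0.0, 1.0) or c in (0.0, 1.0):
        raise ValueError(
            "d' undefined for proportions of exactly 0 or 1 (pass clamp_n to clamp)"
        )
    return float(norm.ppf(s) - norm.ppf(1.0 - c))


def ppv(sensitivity: float, specificity: float, prevalence: float) -> Optional[float]:
    """Positive predictive value at a given prevalence.

    Returns ``None`` (undefined) when no positive diagnoses can occur, i.e.
    the denominator sens*prev + (1-spec)*(1-prev) is zero.
    """
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    num = sensitivity * prevalence
    den = num + (1.0 - specificity) * (1.0 - prevalence)
    if den == 0.0:
        return None
    return num / den


@dataclass(frozen=True)
class PPVCurve:
    """PPV of one method across prevalences, from a fixed operating point."""

    method: str
    sensitivity: float
    specificity: float

    def at(self, prevalence: float) -> Optional[float]:
        return ppv(self.sensitivity, self.specificity, prevalence)

    def table(self, prevalences: Sequence[float]) -> dict[float, Optional[float]]:
        return {p: self.at(p) for p in prevalences}


def d_prime_table(
    methods: Sequence[tuple[str, float, float]] | None = None,
) -> pd.DataFrame:
    """Sensitivity/specificity/d' comparison table across methods.

    Defaults to the three published comparators.  Columns: method,
    sensitivity, specificity, d_prime.
    """
    if methods is None:
        methods = [(name, s, c) for name, (s, c) in PUBLISHED_METHODS.items()]
    rows = [
        {"method": name, "sensitivity": s, "specificity": c, "d_prime": d_prime(s, c)}
        for name, s, c in methods
    ]
    return pd.DataFrame(rows, columns=["method", "sensitivity", "specificity", "d_prime"])


def ppv_table(
    methods: Sequence[tuple[str, float, float]] | None = None,
    prevalences: Sequence[float] = PUBLISHED_PREVALENCES,
) -> pd.DataFrame:
    """Long-form PPV comparison table: one row per (prevalence, method)."""
    if methods is None:
        methods = [(name, s, c) for name, (s, c) in PUBLISHED_METHODS.items()]
    rows = [
        {"method": name, "prevalence": p, "ppv": ppv(s, c, p)}
        for p in prevalences
        for name, s, c in methods
    ]
    return pd.DataFrame(rows, columns=["method", "prevalence", "ppv"])


def format_comparison(df: pd.DataFrame, decimals: int = 3) -> str:
    """Aligned plain-text rendering of a comparison table."""
    if df.empty:
        return ""
    return df.round(decimals).to_string(index=False)
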