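"""Seedable simulator of exposed and control audiometric cohorts.

No real claimant data ship with this package, so the training,
cross-validation and evaluation pipeline is exercised on synthetic cohorts
that emulate the statistical structure described for the study populations:

* controls follow the age-associated hearing loss (AAHL) expectation plus a
  per-individual susceptibility offset and per-measurement noise, with no
  systematic ear asymmetry;
* exposed (noise-damaged) individuals additionally carry either an
  audiometric notch — a Gaussian-in-log-frequency bump centered at 3, 4 or
  6 kHz — or a progressive high-frequency loss rising above 2 kHz, plus a
  systematic left-ear excess at 3-8 kHz (rifle firing from the right
  shoulder shields the right ear, so the left ear is typically worse).

All thresholds are quantized to the clinical 5-dB step and clipped to the
audiometer range.  Ages are uniform on 29-60 years and the default cohort
sizes (143/93 training, 142/92 test) mirror the study databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .audiograms import (
    FREQUENCIES_KHZ,
    HTL_MAX,
    HTL_MIN,
    AAHLTable,
    Audiogram,
    Cohort,
    Individual,
)

#: Frequencies (kHz) that carry the systematic left-ear excess.
HIGH_FREQUENCIES_KHZ: tuple[int, ...] = (3, 4, 6, 8)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model (all dB quantities in dB HL).

    The defaults define this package's reference study conditions: cohort
    sizes and the age range mirror the study databases; effect sizes are
    plausible clinical magnitudes for compensation-claim populations
    (notches of ~25 dB, high-frequency slopes of ~10 dB/octave, ~5 dB mean
    left-ear excess) since the source databases' distributions were never
    published.
    """

    n_exposed: int = 143
    n_control: int = 93
    age_range: tuple[int, int] = (29, 60)
    individual_susceptibility_sd: float = 6.0
    measurement_noise_sd: float = 4.0
    notch_probability: float = 0.6
    notch_center_weights: Mapping[int, float] = field(
        default_factory=lambda: {3: 0.25, 4: 0.5, 6: 0.25}
    )
    notch_depth_mean: float = 25.0
    notch_depth_sd: float = 8.0
    notch_width_octaves: float = 0.5
    hf_slope_mean: float = 10.0
    hf_slope_sd: float = 3.0
    left_excess_mean: float = 5.0
    left_excess_sd: float = 3.0
    quantization_step: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exposed < 1 or self.n_control < 1:
            raise ValueError("cohort sizes must be positive")
        if not (0.0 <= self.notch_probability <= 1.0):
            raise ValueError("notch_probability must lie in [0, 1]")
        for name in (
            "individual_susceptibility_sd",
            "measurement_noise_sd",
            "notch_depth_sd",
            "hf_slope_sd",
            "left_excess_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.notch_width_octaves <= 0 or self.quantization_step <= 0:
            raise ValueError("notch width and quantization step must be positive")
        if not set(self.notch_center_weights) <= {3, 4, 6}:
            raise ValueError("notch centers must be a subset of {3, 4, 6} kHz")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (low, high)")


def _quantize(htl: np.ndarray, step: float) -> np.ndarray:
    return np.clip(np.round(htl / step) * step, HTL_MIN, HTL_MAX)


def _notch_shape(depth: float, center_khz: float, width_octaves: float) -> np.ndarray:
    """Gaussian bump in log2-frequency, evaluated at the six frequencies."""
    octaves = np.log2(np.array(FREQUENCIES_KHZ, dtype=float) / center_khz)
    return depth * np.exp(-(octaves**2) / (2.0 * width_octaves**2))


def _hf_slope_shape(slope_db_per_octave: float) -> np.ndarray:
    """Loss rising linearly (dB per octave) above 2 kHz, zero at and below."""
    octaves_above_2k = np.maximum(
        np.log2(np.array(FREQUENCIES_KHZ, dtype=float) / 2.0), 0.0
    )
    return slope_db_per_octave * octaves_above_2k


def _baseline_pair(
    rng: np.random.Generator, age: int, table: AAHLTable, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Un-quantized right/left HTL vectors of a non-exposed ear pair."""
    aahl = table.lookup_all(age)
    offset = rng.normal(0.0, config.individual_susceptibility_sd)
    right = aahl + offset + rng.normal(0.0, config.measurement_noise_sd, 6)
    left = aahl + offset + rng.normal(0.0, config.measurement_noise_sd, 6)
    return right, left


def _make_individual(
    ident: str,
    age: int,
    right: np.ndarray,
    left: np.ndarray,
    group: str,
    step: float,
) -> Individual:
    right_q = _quantize(right, step)
    left_q = _quantize(left, step)
    return Individual(
        id=ident,
        age=age,
        right=Audiogram(dict(zip(FREQUENCIES_KHZ, right_q))),
        left=Audiogram(dict(zip(FREQUENCIES_KHZ, left_q))),
        group=group,  # type: ignore[arg-type]
    )


def simulate_control(
    config: SimulationConfig,
    table: AAHLTable,
    rng: np.random.Generator | None = None,
    name: str = "control",
    id_prefix: str = "C",
) -> Cohort:
    """Cohort of individuals screened to exclude significant noise exposure."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    individuals = []
    for i in range(config.n_control):
        age = int(rng.integers(lo, hi + 1))
        right, left = _baseline_pair(rng, age, table, config)
        individuals.append(
            _make_individual(
                f"{id_prefix}{i + 1:04d}", age, right, left, "control",
                config.quantization_step,
            )
        )
    return Cohort(individuals, name=name)


def simulate_exposed(
    config: SimulationConfig,
    table: AAHLTable,
    rng: np.random.Generator | None = None,
    name: str = "exposed",
    id_prefix: str = "E",
) -> Cohort:
    """Cohort of noise-exposed individuals with NIHL audiogram features.

    Each individual receives the control baseline plus either a notch
    (probability ``notch_probability``) or a high-frequency sloping loss,
    applied to both ears, plus a left-ear excess at 3-8 kHz.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    centers = sorted(config.notch_center_weights)
    center_p = np.array([config.notch_center_weights[c] for c in centers], dtype=float)
    center_p = center_p / center_p.sum()
    individuals = []
    for i in range(config.n_exposed):
        age = int(rng.integers(lo, hi + 1))
        right, left = _baseline_pair(rng, age, table, config)
        if rng.random() < config.notch_probability:
            center = centers[rng.choice(len(centers), p=center_p)]
            depth = max(rng.normal(config.notch_depth_mean, config.notch_depth_sd), 0.0)
            nihl = _notch_shape(depth, center, config.notch_width_octaves)
        else:
            slope = max(rng.normal(config.hf_slope_mean, config.hf_slope_sd), 0.0)
            nihl = _hf_slope_shape(slope)
        right = right + nihl
        left = left + nihl
        excess = rng.normal(config.left_excess_mean, config.left_excess_sd)
        for f in HIGH_FREQUENCIES_KHZ:
            left[FREQUENCIES_KHZ.index(f)] += excess
        individuals.append(
            _make_individual(
                f"{id_prefix}{i + 1:04d}", age, right, left, "exposed",
                config.quantization_step,
            )
        )
    return Cohort(individuals, name=name)


def simulate_study(
    config: SimulationConfig,
    table: AAHLTable,
    test_sizes: tuple[int, int] = (142, 92),
) -> tuple[Cohort, Cohort, Cohort, Cohort]:
    """Four independent cohorts mirroring the study layout.

    Returns ``(train_exposed, train_control, test_exposed, test_control)``
    with sizes ``(config.n_exposed, config.n_control) + test_sizes``
    (defaults 143/93/142/92).  The four cohorts use disjoint random streams
    derived from ``config.seed`` and disjoint id prefixes.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    test_config = replace(config, n_exposed=test_sizes[0], n_control=test_sizes[1])
    return (
        simulate_exposed(
            config, table, np.random.default_rng(seeds[0]),
            name="train_exposed", id_prefix="TRE",
        ),
        simulate_control(
            config, table, np.random.default_rng(seeds[1]),
            name="train_control", id_prefix="TRC",
        ),
        simulate_exposed(
            test_config, table, np.random.default_rng(seeds[2]),
            name="test_exposed", id_prefix="TEE",
        ),
        simulate_control(
            test_config, table, np.random.default_rng(seeds[3]),
            name="test_control", id_prefix="TEC",
        ),
    )
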