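"""Small fully-connected networks for audiogram-based diagnosis.

The architecture family is deliberately tiny: 1-5 hidden layers of 2-5
units each (every hidden layer has the same width), tanh hidden
activations, and a single sigmoid output unit whose value is the
probability of noise-induced hearing loss.  A :class:`ModelBundle` packages
everything needed to diagnose an individual: architecture, parameters, the
frozen training-set normalization statistics, the feature set, and the
decision threshold.

Bundles are stored as sectioned plain text so that every weight of a
medicolegally relevant model can be audited by eye.  The package ships the
published 18-input, one-hidden-layer, two-unit network ("MLP(18)") as a
bundle fixture; see :func:`published_mlp18`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
import numpy as np

from .audiograms import AAHLTable, Individual
from .features import FeatureSpec, FeatureVector, NormalizationStats, build_features, normalize

HIDDEN_LAYER_RANGE = (1, 5)
HIDDEN_UNIT_RANGE = (2, 5)


class BundleFormatError(ValueError):
    """A model bundle file is missing sections or malformed."""


@dataclass(frozen=True)
class MLPArchitecture:
    """Shape of the network; activations are fixed (tanh hidden, sigmoid out)."""

    n_inputs: int
    hidden_layers: int
    hidden_units: int

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be positive")
        lo, hi = HIDDEN_LAYER_RANGE
        if not (lo <= self.hidden_layers <= hi):
            raise ValueError(f"hidden_layers must be in [{lo}, {hi}]")
        lo, hi = HIDDEN_UNIT_RANGE
        if not (lo <= self.hidden_units <= hi):
            raise ValueError(f"hidden_units must be in [{lo}, {hi}]")

    @property
    def layer_sizes(self) -> list[int]:
        """Unit counts per layer, input through output."""
        return [self.n_inputs] + [self.hidden_units] * self.hidden_layers + [1]


@dataclass
class MLPParameters:
    """Per-layer weight matrices (to-units x from-units) and bias vectors."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases):
            raise ValueError("weights and biases must have one entry per layer")
        self.weights = [np.asarray(W, dtype=float) for W in self.weights]
        self.biases = [np.asarray(b, dtype=float) for b in self.biases]
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.ndim != 2 or b.shape != (W.shape[0],):
                raise ValueError(f"layer {i + 1}: inconsistent weight/bias shapes")
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                raise ValueError(f"layer {i + 1}: non-finite parameter")
            if i > 0 and W.shape[1] != self.weights[i - 1].shape[0]:
                raise ValueError(f"layer {i + 1}: input size mismatch with layer {i}")

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def matches(self, arch: MLPArchitecture) -> bool:
        sizes = arch.layer_sizes
        return all(
            W.shape == (sizes[i + 1], sizes[i]) for i, W in enumerate(self.weights)
        )

    def copy(self) -> "MLPParameters":
        return MLPParameters(
            [W.copy() for W in self.weights], [b.copy() for b in self.biases]
        )

    def sum_squared_weights(self) -> float:
        """Sum of squared connection weights (biases excluded)."""
        return float(sum(np.sum(W**2) for W in self.weights))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable split form
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward_batch(
    params: MLPParameters, X: np.ndarray, return_activations: bool = False
):
    """Probabilities for a batch of normalized feature rows.

    Hidden layers apply ``tanh(W a + b)``; the output unit applies the
    logistic sigmoid.  With ``return_activations`` the per-layer activations
    (input included) and the output logit are also returned, for use by the
    trainer's backward pass.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.weights[0].shape[1]:
        raise ValueError(
            f"input dimension {X.shape[1]} != network input size "
            f"{params.weights[0].shape[1]}"
        )
    activations = [X]
    a = X
    for W, b in zip(params.weights[:-1], params.biases[:-1]):
        a = np.tanh(a @ W.T + b)
        activations.append(a)
    logit = a @ params.weights[-1].T + params.biases[-1]
    p = _sigmoid(logit)[:, 0]
    if return_activations:
        return p, activations, logit[:, 0]
    return p


def forward(params: MLPParameters, arch: MLPArchitecture, x: np.ndarray) -> float:
    """Output probability for a single normalized feature vector."""
    if not params.matches(arch):
        raise ValueError("parameters do not match the declared architecture")
    x = np.asarray(x, dtype=float)
    if x.shape != (arch.n_inputs,):
        raise ValueError(f"expected input of shape ({arch.n_inputs},), got {x.shape}")
    return float(forward_batch(params, x[None, :])[0])


@dataclass
class ModelBundle:
    """Everything needed to diagnose an individual with a trained network."""

    architecture: MLPArchitecture
    parameters: MLPParameters
    stats: NormalizationStats
    feature_spec: FeatureSpec
    threshold: float = 0.5
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly in (0, 1)")
        if self.feature_spec.dimension != self.architecture.n_inputs:
            raise ValueError(
                f"feature set {self.feature_spec.name!r} has dimension "
                f"{self.feature_spec.dimension}, architecture expects "
                f"{self.architecture.n_inputs}"
            )
        if self.stats.dimension != self.architecture.n_inputs:
            raise ValueError("normalization stats dimension mismatch")
        if not self.parameters.matches(self.architecture):
            raise ValueError("parameters do not match the architecture")


@dataclass(frozen=True)
class Diagnosis:
    """Outcome of classifying one individual."""

    id: str
    probability: float
    positive: bool

    @property
    def label(self) -> str:
        return "positive" if self.positive else "negative"


def classify(bundle: ModelBundle, ind: Individual, table: AAHLTable) -> Diagnosis:
    """Diagnose one individual.

    Features are built per the bundle's feature set, z-scored with the
    bundle's frozen training statistics and passed through the network.  A
    probability at or above the threshold is a positive diagnosis (ties
    break toward sensitivity, the medicolegally conservative direction).
    """
    v = build_features(ind, bundle.feature_spec, table)
    z = normalize(v, bundle.stats)
    p = forward(bundle.parameters, bundle.architecture, z.values)
    return Diagnosis(id=ind.id, probability=p, positive=p >= bundle.threshold)


# ---------------------------------------------------------------------------
# Bundle serialization: sectioned, human-auditable plain text

_MAGIC = "nihlnet-model-bundle v1"


def _fmt_vector(v: np.ndarray) -> str:
    return " ".join(repr(float(x)) for x in v)


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Write a bundle as sectioned plain text (lossless round trip)."""
    lines = [_MAGIC, ""]
    if bundle.provenance:
        lines.append("[provenance]")
        lines.extend(bundle.provenance.splitlines())
        lines.append("")
    lines += [
        "[feature_spec]",
        f"name = {bundle.feature_spec.name}",
        "",
        "[architecture]",
        f"n_inputs = {bundle.architecture.n_inputs}",
        f"hidden_layers = {bundle.architecture.hidden_layers}",
        f"hidden_units = {bundle.architecture.hidden_units}",
        "",
        "[threshold]",
        f"value = {bundle.threshold!r}",
        "",
        f"[normalization_means n={bundle.stats.dimension}]",
        _fmt_vector(bundle.stats.means),
        f"[normalization_sds n={bundle.stats.dimension}]",
        _fmt_vector(bundle.stats.sds),
        "",
    ]
    for i, (W, b) in enumerate(zip(bundle.parameters.weights, bundle.parameters.biases), 1):
        lines.append(f"[weights layer={i} shape={W.shape[0]}x{W.shape[1]}]")
        lines.extend(_fmt_vector(row) for row in W)
        lines.append(f"[biases layer={i} n={len(b)}]")
        lines.append(_fmt_vector(b))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("[") and stripped.endswith("]"):
            current = sections.setdefault(stripped[1:-1], [])
        elif current is not None and stripped:
            current.append(stripped)
    return sections


def _require(sections: dict[str, list[str]], key: str) -> list[str]:
    if key not in sections:
        raise BundleFormatError(f"missing section [{key}]")
    return sections[key]


def _kv(lines: list[str], key: str, section: str) -> str:
    for line in lines:
        if "=" in line:
            k, v = line.split("=", 1)
            if k.strip() == key:
                return v.strip()
    raise BundleFormatError(f"missing key {key!r} in section [{section}]")


def load_bundle(path: str | Path) -> ModelBundle:
    """Load a bundle written by :func:`save_bundle`.

    Numeric values are parsed exactly as printed, so a fixture transcribing
    published three-decimal weights loads to those decimals bit-exactly.
    """
    text = Path(path).read_text()
    return _load_bundle_text(text)


def _load_bundle_text(text: str) -> ModelBundle:
    first = text.lstrip().splitlines()[0].strip() if text.strip() else ""
    if first != _MAGIC:
        raise BundleFormatError(f"not a model bundle (expected header {_MAGIC!r})")
    sections = _parse_sections(text)

    spec = FeatureSpec(_kv(_require(sections, "feature_spec"), "name", "feature_spec"))
    arch_lines = _require(sections, "architecture")
    try:
        arch = MLPArchitecture(
            n_inputs=int(_kv(arch_lines, "n_inputs", "architecture")),
            hidden_layers=int(_kv(arch_lines, "hidden_layers", "architecture")),
            hidden_units=int(_kv(arch_lines, "hidden_units", "architecture")),
        )
        threshold = float(_kv(_require(sections, "threshold"), "value", "threshold"))
        means = np.array(
            _require(sections, f"normalization_means n={arch.n_inputs}")[0].split(),
            dtype=float,
        )
        sds = np.array(
            _require(sections, f"normalization_sds n={arch.n_inputs}")[0].split(),
            dtype=float,
        )
        sizes = arch.layer_sizes
        weights, biases = [], []
        for i in range(len(sizes) - 1):
            shape = f"{sizes[i + 1]}x{sizes[i]}"
            w_lines = _require(sections, f"weights layer={i + 1} shape={shape}")
            if len(w_lines) != sizes[i + 1]:
                raise BundleFormatError(
                    f"layer {i + 1}: expected {sizes[i + 1]} weight rows, got {len(w_lines)}"
                )
            weights.append(np.array([row.split() for row in w_lines], dtype=float))
            b_lines = _require(sections, f"biases layer={i + 1} n={sizes[i + 1]}")
            biases.append(np.array(b_lines[0].split(), dtype=float))
        params = MLPParameters(weights, biases)
    except BundleFormatError:
        raise
    except (ValueError, IndexError) as exc:
        raise BundleFormatError(f"malformed bundle: {exc}") from exc

    provenance = "\n".join(sections.get("provenance", []))
    return ModelBundle(
        architecture=arch,
        parameters=params,
        stats=NormalizationStats(means, sds, source="loaded from bundle"),
        feature_spec=spec,
        threshold=threshold,
        provenance=provenance,
    )


def published_mlp18() -> ModelBundle:
    """The published 18-input, 1-hidden-layer, 2-unit diagnostic network.

    Weights and biases are the published three-decimal values.  The
    normalization statistics bundled with it are a synthetic stand-in
    (fitted on this package's reference simulated cohorts): the original
    training databases and their per-feature means/SDs were never released,
    so per-individual outputs of this bundle will not exactly match the
    authors' tool on real claimants.  The bundle's provenance text repeats
    this warning.
    """
    text = (
        resources.files("nihlnet.data").joinpath("mlp18_bundle.txt").read_text()
    )
    return _load_bundle_text(text)
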