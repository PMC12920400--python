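"""0-1 activation policy networks and observational datasets.

A prescriptive policy network is a shallow feed-forward network whose hidden
units use the indicator activation ``sigma(z) = 1[z >= 0]`` and whose output
layer produces one affine score per treatment.  At inference the prescribed
treatment is the argmax of the output scores (ties broken toward the lowest
treatment index), which is the deterministic analogue of the one-hot output
enforced during MIP training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Hashable, Sequence

import numpy as np

__all__ = [
    "TreatmentSet",
    "NetworkArchitecture",
    "NetworkParameters",
    "PolicyNetwork",
    "ObservationalDataset",
    "forward_activations",
    "forward_hidden",
    "forward_scores",
    "forward_policy",
]


@dataclass(frozen=True)
class TreatmentSet:
    """Ordered set of distinct treatment labels.

    The order is fixed and persisted; index positions 0..|T|-1 are used for
    score columns and the inference tie-break (lowest index wins).
    """

    labels: tuple

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("a treatment set needs at least two labels")
        if len(set(labels)) != len(labels):
            raise ValueError("treatment labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def index(self, label: Hashable) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown treatment label: {label!r}") from None

    def indices_of(self, labels: Sequence) -> np.ndarray:
        """Vector of treatment indices for an array of labels."""
        lookup = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.array([lookup[lab] for lab in labels], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown treatment label: {exc.args[0]!r}") from None


@dataclass(frozen=True)
class NetworkArchitecture:
    """Shape of a policy network: F inputs, K-wide hidden layers, |T| outputs.

    ``n_hidden_layers`` counts hidden (indicator-activated) layers; the affine
    output layer comes on top, so a "depth 2" network (the usual choice) has
    ``n_hidden_layers=1``.
    """

    n_features: int
    width: int
    n_hidden_layers: int
    treatments: TreatmentSet

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if self.n_hidden_layers < 1:
            raise ValueError("need at least one hidden layer")

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)


@dataclass
class NetworkParameters:
    """Weights and biases of a policy network, all within ``weight_bounds``."""

    input_weights: np.ndarray  # (F, K)
    hidden_weights: list  # [(K, K)] * (n_hidden_layers - 1)
    output_weights: np.ndarray  # (K, |T|)
    hidden_biases: list  # [(K,)] * n_hidden_layers
    output_biases: np.ndarray  # (|T|,)
    weight_bounds: tuple = (-1.0, 1.0)

    def __post_init__(self) -> None:
        self.input_weights = np.asarray(self.input_weights, dtype=float)
        self.hidden_weights = [np.asarray(w, dtype=float) for w in self.hidden_weights]
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        self.hidden_biases = [np.asarray(b, dtype=float) for b in self.hidden_biases]
        self.output_biases = np.asarray(self.output_biases, dtype=float)

    def validate(self, arch: NetworkArchitecture, atol: float = 1e-7) -> None:
        F, K, T = arch.n_features, arch.width, arch.n_treatments
        if self.input_weights.shape != (F, K):
            raise ValueError(f"input_weights shape {self.input_weights.shape} != {(F, K)}")
        if len(self.hidden_weights) != arch.n_hidden_layers - 1:
            raise ValueError("wrong number of hidden weight matrices")
        for w in self.hidden_weights:
            if w.shape != (K, K):
                raise ValueError(f"hidden weight shape {w.shape} != {(K, K)}")
        if self.output_weights.shape != (K, T):
            raise ValueError(f"output_weights shape {self.output_weights.shape} != {(K, T)}")
        if len(self.hidden_biases) != arch.n_hidden_layers:
            raise ValueError("wrong number of hidden bias vectors")
        for b in self.hidden_biases:
            if b.shape != (K,):
                raise ValueError(f"hidden bias shape {b.shape} != {(K,)}")
        if self.output_biases.shape != (T,):
            raise ValueError(f"output_biases shape {self.output_biases.shape} != {(T,)}")
        lo, hi = self.weight_bounds
        if not lo < hi:
            raise ValueError("weight_bounds must satisfy lower < upper")
        for name, arr in self._all_arrays():
            if arr.size and (arr.min() < lo - atol or arr.max() > hi + atol):
                raise ValueError(f"{name} outside weight bounds [{lo}, {hi}]")

    def _all_arrays(self):
        yield "input_weights", self.input_weights
        for i, w in enumerate(self.hidden_weights):
            yield f"hidden_weights[{i}]", w
        yield "output_weights", self.output_weights
        for i, b in enumerate(self.hidden_biases):
            yield f"hidden_biases[{i}]", b
        yield "output_biases", self.output_biases


@dataclass
class PolicyNetwork:
    """A trained (or hand-built) prescriptive policy network."""

    architecture: NetworkArchitecture
    parameters: NetworkParameters
    activation_threshold: float = 1e-4  # epsilon margin used at training time
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parameters.validate(self.architecture)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        a, p = self.architecture, self.parameters
        doc = {
            "format": "pnn-policy-network",
            "version": 1,
            "architecture": {
                "n_features": a.n_features,
                "width": a.width,
                "n_hidden_layers": a.n_hidden_layers,
                "treatments": list(a.treatments.labels),
            },
            "parameters": {
                "input_weights": p.input_weights.tolist(),
                "hidden_weights": [w.tolist() for w in p.hidden_weights],
                "output_weights": p.output_weights.tolist(),
                "hidden_biases": [b.tolist() for b in p.hidden_biases],
                "output_biases": p.output_biases.tolist(),
                "weight_bounds": list(p.weight_bounds),
            },
            "activation_threshold": self.activation_threshold,
            "metadata": self.metadata,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PolicyNetwork":
        doc = json.loads(text)
        if doc.get("format") != "pnn-policy-network":
            raise ValueError("not a policy-network document")
        a = doc["architecture"]
        arch = NetworkArchitecture(
            n_features=a["n_features"],
            width=a["width"],
            n_hidden_layers=a["n_hidden_layers"],
            treatments=TreatmentSet(tuple(a["treatments"])),
        )
        p = doc["parameters"]
        params = NetworkParameters(
            input_weights=p["input_weights"],
            hidden_weights=p["hidden_weights"],
            output_weights=p["output_weights"],
            hidden_biases=p["hidden_biases"],
            output_biases=p["output_biases"],
            weight_bounds=tuple(p["weight_bounds"]),
        )
        return cls(
            architecture=arch,
            parameters=params,
            activation_threshold=doc.get("activation_threshold", 1e-4),
            metadata=doc.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "PolicyNetwork":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass
class ObservationalDataset:
    """Rows (X_i, t_i, y_i) plus the declared optimization direction."""

    covariates: np.ndarray  # (n, F)
    treatments: np.ndarray  # (n,) labels
    outcomes: np.ndarray  # (n,)
    direction: str = "maximize"
    treatment_set: TreatmentSet | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.covariates, dtype=float)
        if X.ndim != 2:
            raise ValueError("covariates must be a 2-D matrix")
        self.covariates = X
        self.treatments = np.asarray(self.treatments)
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        n = X.shape[0]
        if n < 1:
            raise ValueError("dataset must contain at least one row")
        if self.treatments.shape != (n,) or self.outcomes.shape != (n,):
            raise ValueError("covariates, treatments and outcomes must align row-wise")
        if not np.isfinite(X).all() or not np.isfinite(self.outcomes).all():
            raise ValueError("covariates and outcomes must be finite")
        if self.direction not in ("maximize", "minimize"):
            raise ValueError("direction must be 'maximize' or 'minimize'")
        if self.treatment_set is None:
            # label order = first appearance in the data
            seen: dict = {}
            for lab in self.treatments.tolist():
                seen.setdefault(lab, None)
            self.treatment_set = TreatmentSet(tuple(seen))
        # raises on labels outside the declared set
        self._treatment_idx = self.treatment_set.indices_of(self.treatments.tolist())

    @property
    def n(self) -> int:
        return self.covariates.shape[0]

    @property
    def n_features(self) -> int:
        return self.covariates.shape[1]

    @property
    def treatment_indices(self) -> np.ndarray:
        """Observed treatments as indices into the treatment set."""
        return self._treatment_idx


# ---------------------------------------------------------------------------
# forward passes


def _check_features(net: PolicyNetwork, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2 or X.shape[1] != net.architecture.n_features:
        raise ValueError(
            f"expected {net.architecture.n_features} features, got shape {X.shape}"
        )
    return X


def forward_hidden(net: PolicyNetwork, X: np.ndarray) -> list[np.ndarray]:
    """Binary activations of every hidden layer, shape (n, K) each.

    A unit fires iff its pre-activation is >= 0 (sigma(0) = 1).
    """
    X = _check_features(net, X)
    p = net.parameters
    acts = []
    h = (X @ p.input_weights + p.hidden_biases[0] >= 0.0).astype(np.int8)
    acts.append(h)
    for w, b in zip(p.hidden_weights, p.hidden_biases[1:]):
        h = (h @ w + b >= 0.0).astype(np.int8)
        acts.append(h)
    return acts


def forward_scores(net: PolicyNetwork, X: np.ndarray) -> np.ndarray:
    """Affine output scores per treatment, shape (n, |T|). No activation."""
    X = _check_features(net, X)
    h = forward_hidden(net, X)[-1]
    p = net.parameters
    return h @ p.output_weights + p.output_biases


def forward_activations(net: PolicyNetwork, x: np.ndarray):
    """Hidden activations and output pre-activations for a single input.

    Returns ``(hidden, scores)`` where ``hidden`` is a list of binary vectors
    (one per hidden layer) and ``scores`` the length-|T| output vector.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("forward_activations expects a single covariate vector")
    hidden = [h[0] for h in forward_hidden(net, x[None, :])]
    scores = forward_scores(net, x[None, :])[0]
    return hidden, scores


def forward_policy(net: PolicyNetwork, X: np.ndarray) -> np.ndarray:
    """Prescribed treatment labels for each row of ``X``.

    Deterministic: argmax of output scores, ties to the lowest treatment
    index.  An empty input yields an empty assignment vector.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(net.architecture.treatments.labels)
    if X.size == 0 and (X.ndim != 2 or X.shape[0] == 0):
        return labels[np.zeros(0, dtype=np.intp)]
    scores = forward_scores(net, X)
    return labels[np.argmax(scores, axis=1)]
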