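"""Synthetic observational data with known counterfactuals.

The generator draws iid standard-normal covariates and produces both
potential outcomes of a binary treatment through an additive model

    Y(t) = eta(X) + (1/2) * (2t - 1) * kappa(X) + noise,

where ``eta`` is the mean effect and ``kappa`` the treatment effect, both
functions of a feature subset that depends on the experimental design.
Treatments are conditionally randomized: each individual receives their
(realized) optimal treatment with probability ``p_correct`` and the other
arm otherwise, which induces covariate-dependent confounding away from
p_correct = 0.5.

Three standard designs are provided:

=======  ====  ==========================================  ==============================
design    F    eta(x)                                      kappa(x)
=======  ====  ==========================================  ==============================
1          2   x1/2 + x2                                   x1/2
2         10   (x1+x2)/2 + x3+..+x6                        sum_{f<=2} 1{x_f>0} x_f
3         20   (x1+..+x4)/2 + x5+..+x8                     sum_{f<=4} 1{x_f>0} x_f
=======  ====  ==========================================  ==============================

In designs 2 and 3 kappa is non-negative, so treatment 1 is never worse in
expectation; the realized optimum can still be 0 where kappa(x) = 0 because
independent noise is drawn per arm (see ``SimConfig.per_arm_noise``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import norm

from .network import ObservationalDataset, TreatmentSet

__all__ = [
    "DesignSpec",
    "SimConfig",
    "SimulatedDataset",
    "generate_dataset",
    "true_optimal_policy",
    "binarize_onehot_deciles",
    "binarize_adapted",
    "OraclePropensity",
    "OracleOutcome",
]


def _eta_design1(X: np.ndarray) -> np.ndarray:
    return 0.5 * X[:, 0] + X[:, 1]


def _kappa_design1(X: np.ndarray) -> np.ndarray:
    return 0.5 * X[:, 0]


def _eta_design2(X: np.ndarray) -> np.ndarray:
    return 0.5 * X[:, :2].sum(axis=1) + X[:, 2:6].sum(axis=1)


def _kappa_design2(X: np.ndarray) -> np.ndarray:
    x = X[:, :2]
    return np.where(x > 0.0, x, 0.0).sum(axis=1)


def _eta_design3(X: np.ndarray) -> np.ndarray:
    return 0.5 * X[:, :4].sum(axis=1) + X[:, 4:8].sum(axis=1)


def _kappa_design3(X: np.ndarray) -> np.ndarray:
    x = X[:, :4]
    return np.where(x > 0.0, x, 0.0).sum(axis=1)


_DESIGNS = {
    1: (2, _eta_design1, _kappa_design1),
    2: (10, _eta_design2, _kappa_design2),
    3: (20, _eta_design3, _kappa_design3),
}


@dataclass(frozen=True)
class DesignSpec:
    """A generative design: feature count plus mean/treatment effect maps."""

    design_id: int
    n_features: int
    mean_effect: Callable[[np.ndarray], np.ndarray]
    treatment_effect: Callable[[np.ndarray], np.ndarray]

    @classmethod
    def from_id(cls, design_id: int) -> "DesignSpec":
        if design_id not in _DESIGNS:
            raise ValueError(f"unknown design id {design_id}; choose from 1, 2, 3")
        F, eta, kappa = _DESIGNS[design_id]
        return cls(design_id, F, eta, kappa)

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"design {self.design_id} expects {self.n_features} features, "
                f"got shape {X.shape}"
            )
        return X


@dataclass(frozen=True)
class SimConfig:
    """Sampling configuration for one simulated study replicate.

    ``noise`` is the scale of the Gaussian outcome noise; by default it is
    read as a variance (0.01, i.e. sd 0.1); set ``noise_is_sd`` to reinterpret
    it as a standard deviation.  ``per_arm_noise`` draws independent noise for
    each treatment arm so the realized optimal arm is almost surely unique.
    """

    n_train: int = 100
    n_test: int = 10_000
    p_correct: float = 0.5
    noise: float = 0.01
    noise_is_sd: bool = False
    per_arm_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_test < 0:
            raise ValueError("sample sizes must be positive")
        if not 0.0 < self.p_correct < 1.0:
            raise ValueError("p_correct must lie in (0, 1)")
        if self.noise < 0.0:
            raise ValueError("noise must be nonnegative")

    @property
    def noise_sd(self) -> float:
        return self.noise if self.noise_is_sd else float(np.sqrt(self.noise))


@dataclass
class SimulatedDataset:
    """Observational rows plus the withheld counterfactual side-car."""

    data: ObservationalDataset
    potential_outcomes: np.ndarray  # (n, 2): columns Y(0), Y(1)
    optimal_treatment: np.ndarray  # (n,) in {0, 1}

    def __post_init__(self) -> None:
        n = self.data.n
        self.potential_outcomes = np.asarray(self.potential_outcomes, dtype=float)
        self.optimal_treatment = np.asarray(self.optimal_treatment, dtype=np.intp)
        if self.potential_outcomes.shape != (n, 2):
            raise ValueError("potential_outcomes must have shape (n, 2)")
        if self.optimal_treatment.shape != (n,):
            raise ValueError("optimal_treatment must have length n")
        obs = self.potential_outcomes[np.arange(n), self.data.treatment_indices]
        if not np.array_equal(obs, self.data.outcomes):
            raise ValueError("observed outcomes must equal the observed-arm potential outcome")


def _draw(design: DesignSpec, cfg: SimConfig, n: int, rng: np.random.Generator) -> SimulatedDataset:
    X = rng.standard_normal((n, design.n_features))
    eta = design.mean_effect(X)
    kappa = design.treatment_effect(X)
    sd = cfg.noise_sd
    if cfg.per_arm_noise:
        eps0 = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        eps1 = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
    else:
        eps0 = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        eps1 = eps0
    y0 = eta - 0.5 * kappa + eps0
    y1 = eta + 0.5 * kappa + eps1
    po = np.column_stack([y0, y1])
    optimal = np.argmax(po, axis=1)  # tie -> arm 0
    correct = rng.random(n) < cfg.p_correct
    observed = np.where(correct, optimal, 1 - optimal)
    outcomes = po[np.arange(n), observed]
    data = ObservationalDataset(
        covariates=X,
        treatments=observed,
        outcomes=outcomes,
        direction="maximize",
        treatment_set=TreatmentSet((0, 1)),
    )
    return SimulatedDataset(data=data, potential_outcomes=po, optimal_treatment=optimal)


def generate_dataset(design: DesignSpec, cfg: SimConfig):
    """Draw a (train, test) pair of simulated observational datasets.

    Fully reproducible from ``cfg.seed``: the train and test splits are drawn
    from independent child streams of a single seed sequence.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_train, rng_test = (np.random.default_rng(s) for s in ss.spawn(2))
    train = _draw(design, cfg, cfg.n_train, rng_train)
    test = _draw(design, cfg, cfg.n_test, rng_test) if cfg.n_test > 0 else None
    return train, test


def true_optimal_policy(design: DesignSpec, X: np.ndarray) -> np.ndarray:
    """Noiseless Bayes policy 1{kappa(x) > 0}; ties go to arm 0."""
    X = design._check(X)
    return (design.treatment_effect(X) > 0.0).astype(np.intp)


# ---------------------------------------------------------------------------
# binarization transforms used by tree-style benchmarks

_DECILE_EDGES = norm.ppf(np.arange(1, 10) / 10.0)  # Phi^{-1}(0.1 .. 0.9)


def binarize_onehot_deciles(X: np.ndarray) -> np.ndarray:
    """One-hot decile encoding against theoretical N(0,1) decile boundaries.

    Bins are left-open/right-closed, so a value exactly on a boundary falls in
    the lower bin (x = 0 lands in decile 5).  Output shape is (n, 10 F) with
    exactly one hot column per feature block.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D covariate matrix")
    if not np.isfinite(X).all():
        raise ValueError("covariates must be finite for decile binarization")
    n, F = X.shape
    # number of edges strictly below x = 0-based bin in (edge[j-1], edge[j]]
    bins = np.searchsorted(_DECILE_EDGES, X, side="left")
    out = np.zeros((n, 10 * F), dtype=np.int8)
    rows = np.repeat(np.arange(n), F)
    cols = (np.arange(F) * 10 + bins).ravel()
    out[rows, cols] = 1
    return out


def binarize_adapted(onehot: np.ndarray) -> np.ndarray:
    """Thermometer (cumulative) encoding of a decile one-hot matrix.

    Within each feature's 10-column block, the hot position propagates
    rightward: one-hot at j becomes ones at j..10.
    """
    onehot = np.asarray(onehot)
    if onehot.ndim != 2 or onehot.shape[1] % 10 != 0:
        raise ValueError("expected an (n, 10F) one-hot decile matrix")
    n, cols = onehot.shape
    blocks = onehot.reshape(n, cols // 10, 10)
    if not np.all(blocks.sum(axis=2) == 1) or not np.isin(onehot, (0, 1)).all():
        raise ValueError("each 10-column block must be one-hot")
    return np.maximum.accumulate(blocks, axis=2).reshape(n, cols).astype(np.int8)


# ---------------------------------------------------------------------------
# oracle nuisance models (true generative quantities, for validation)


class OraclePropensity:
    """True conditional assignment probabilities of the simulator.

    The observed arm equals the realized optimal arm with probability
    p_correct, and P(optimal = 1 | X) = Phi(kappa(x) / sd(delta)) where delta
    is the noise difference between arms, so

        P(T=1 | X) = p * P(opt=1|X) + (1-p) * (1 - P(opt=1|X)).
    """

    def __init__(self, design: DesignSpec, cfg: SimConfig):
        self.design = design
        self.cfg = cfg

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self.design._check(X)
        kappa = self.design.treatment_effect(X)
        sd = self.cfg.noise_sd
        if self.cfg.per_arm_noise and sd > 0:
            p_opt1 = norm.cdf(kappa / (np.sqrt(2.0) * sd))
        else:
            # shared (or zero) noise: the optimum is deterministic given X;
            # exact ties (kappa == 0) resolve to arm 0
            p_opt1 = (kappa > 0.0).astype(float)
        p = self.cfg.p_correct
        p1 = p * p_opt1 + (1.0 - p) * (1.0 - p_opt1)
        return np.column_stack([1.0 - p1, p1])


class OracleOutcome:
    """True arm-wise mean outcomes eta(x) -/+ kappa(x)/2."""

    def __init__(self, design: DesignSpec):
        self.design = design

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = self.design._check(X)
        eta = self.design.mean_effect(X)
        kappa = self.design.treatment_effect(X)
        return np.column_stack([eta - 0.5 * kappa, eta + 0.5 * kappa])
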