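"""Counterfactual score estimation: IPW, direct method, and doubly robust.

Observational data only reveals the outcome of the treatment an individual
actually received.  To score an arbitrary policy we build a per-individual,
per-treatment table of counterfactual scores psi_t(z_i) using one of three
estimators:

* **IPW** — inverse propensity weighting of observed outcomes,
  psi_t(z_i) = 1{t_i = t} y_i / p(t | x_i);
* **direct method (DM)** — arm-wise outcome regressions,
  psi_t(z_i) = mu_t(x_i);
* **doubly robust (DR / AIPW)** — the augmented combination
  psi_t(z_i) = mu_t(x_i) + 1{t_i = t} (y_i - mu_t(x_i)) / p(t | x_i),
  unbiased when either nuisance model is correct.

Propensities are clipped below at ``clip_floor`` before any division to
control the variance of the IPW correction.  The value of a policy s is the
mean of the psi entries it selects; its advantage over a baseline policy is
the difference of the two values on the same table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import KFold, StratifiedKFold

from .network import ObservationalDataset, TreatmentSet

__all__ = [
    "PropensityModel",
    "OutcomeModel",
    "CounterfactualTable",
    "PositivityError",
    "fit_nuisance",
    "score_table",
    "dr_score_table",
    "ipw_value",
    "dm_value",
    "dr_policy_value",
    "dr_policy_advantage",
    "observed_policy",
]


class PositivityError(ValueError):
    """A treatment arm has no (or too few) observations to support estimation."""


class PropensityModel:
    """Fitted treatment-assignment classifier aligned to a treatment set.

    ``predict_proba`` returns an (n, |T|) matrix whose columns follow the
    treatment-set order; each row sums to 1 before any clipping.
    """

    def __init__(self, estimator, treatment_set: TreatmentSet):
        self.estimator = estimator
        self.treatment_set = treatment_set

    @classmethod
    def fit(cls, estimator, data: ObservationalDataset) -> "PropensityModel":
        ts = data.treatment_set
        present = set(data.treatments.tolist())
        missing = [lab for lab in ts if lab not in present]
        if missing:
            raise PositivityError(
                f"treatment arm(s) {missing} have zero observations; "
                "positivity cannot hold"
            )
        est = clone(estimator)
        est.fit(data.covariates, data.treatment_indices)
        return cls(est, ts)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        raw = self.estimator.predict_proba(X)
        T = len(self.treatment_set)
        out = np.zeros((X.shape[0], T))
        for col, cls_idx in enumerate(self.estimator.classes_):
            out[:, int(cls_idx)] = raw[:, col]
        return out


class OutcomeModel:
    """Arm-wise outcome regressions fit on each arm's subpopulation.

    ``predict`` returns an (n, |T|) matrix of mu_t(x) estimates with columns
    in treatment-set order.
    """

    def __init__(self, estimators: dict, treatment_set: TreatmentSet):
        self.estimators = estimators  # treatment index -> fitted regressor
        self.treatment_set = treatment_set

    @classmethod
    def fit(cls, estimator, data: ObservationalDataset) -> "OutcomeModel":
        ts = data.treatment_set
        idx = data.treatment_indices
        fitted = {}
        for t in range(len(ts)):
            mask = idx == t
            if not mask.any():
                raise PositivityError(
                    f"treatment arm {ts.labels[t]!r} has zero observations"
                )
            est = clone(estimator)
            est.fit(data.covariates[mask], data.outcomes[mask])
            fitted[t] = est
        return cls(fitted, ts)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        T = len(self.treatment_set)
        out = np.empty((X.shape[0], T))
        for t in range(T):
            out[:, t] = self.estimators[t].predict(X)
        return out


@dataclass
class CounterfactualTable:
    """Per-individual, per-treatment scores psi plus the nuisance fits."""

    psi: np.ndarray  # (n, |T|)
    propensity: np.ndarray  # (n, |T|), clipped
    mu: np.ndarray  # (n, |T|)
    method: str  # 'ipw' | 'dm' | 'dr'
    clip_floor: float
    treatment_set: TreatmentSet

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.propensity = np.asarray(self.propensity, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        T = len(self.treatment_set)
        n = self.psi.shape[0]
        for name, arr in (("psi", self.psi), ("propensity", self.propensity), ("mu", self.mu)):
            if arr.shape != (n, T):
                raise ValueError(f"{name} must have shape (n, |T|)")
        if not 0.0 < self.clip_floor < 0.5:
            raise ValueError("clip_floor must lie in (0, 0.5)")
        if self.method not in ("ipw", "dm", "dr"):
            raise ValueError("method must be 'ipw', 'dm' or 'dr'")

    @property
    def n(self) -> int:
        return self.psi.shape[0]

    # -- delimited import/export -------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n):
            for t, lab in enumerate(self.treatment_set):
                rows.append(
                    {
                        "id": i,
                        "treatment": lab,
                        "psi": self.psi[i, t],
                        "propensity": self.propensity[i, t],
                        "mu": self.mu[i, t],
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, method: str = "dr", clip_floor: float = 0.01
    ) -> "CounterfactualTable":
        required = {"id", "treatment", "psi", "propensity", "mu"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"counterfactual table is missing columns: {sorted(missing)}")
        labels = tuple(pd.unique(frame["treatment"]))
        ts = TreatmentSet(labels)
        ids = np.sort(pd.unique(frame["id"]))
        n, T = len(ids), len(labels)
        psi = np.full((n, T), np.nan)
        prop = np.full((n, T), np.nan)
        mu = np.full((n, T), np.nan)
        id_pos = {v: i for i, v in enumerate(ids)}
        for _, row in frame.iterrows():
            i, t = id_pos[row["id"]], ts.index(row["treatment"])
            psi[i, t], prop[i, t], mu[i, t] = row["psi"], row["propensity"], row["mu"]
        if np.isnan(psi).any():
            raise ValueError("counterfactual table has missing (id, treatment) cells")
        return cls(psi, prop, mu, method=method, clip_floor=clip_floor, treatment_set=ts)


# ---------------------------------------------------------------------------
# nuisance model selection


def _cv_splitter(n_folds: int, labels: np.ndarray, seed: int):
    """Stratified folds when every arm supports it, plain K-fold otherwise."""
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() >= n_folds:
        return StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return KFold(n_splits=n_folds, shuffle=True, random_state=seed)


def fit_nuisance(
    train: ObservationalDataset,
    propensity_candidates: list,
    outcome_candidates: list,
    n_folds: int = 10,
    seed: int = 0,
):
    """Select and fit the nuisance models by K-fold cross-validation.

    The propensity candidate with the highest CV classification accuracy and
    the outcome candidate with the lowest CV root-mean-squared error (fit per
    arm on that arm's subpopulation, regress-and-compare style) win.  Returns
    ``(PropensityModel, OutcomeModel, report)`` where the report records every
    candidate's score.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if not propensity_candidates or not outcome_candidates:
        raise ValueError("need at least one candidate per nuisance role")
    idx = train.treatment_indices
    T = len(train.treatment_set)
    arm_counts = np.bincount(idx, minlength=T)
    if (arm_counts == 0).any():
        empty = [train.treatment_set.labels[t] for t in np.flatnonzero(arm_counts == 0)]
        raise PositivityError(f"treatment arm(s) {empty} have zero observations")
    if arm_counts.min() < n_folds:
        raise ValueError(
            f"every arm needs >= n_folds={n_folds} observations for outcome CV; "
            f"smallest arm has {arm_counts.min()}"
        )
    X, y = train.covariates, train.outcomes
    records = []

    # propensity: CV classification accuracy on (X, t)
    prop_scores = []
    splitter = _cv_splitter(n_folds, idx, seed)
    for cand in propensity_candidates:
        hits = 0
        for tr, te in splitter.split(X, idx):
            est = clone(cand)
            est.fit(X[tr], idx[tr])
            hits += int((est.predict(X[te]) == idx[te]).sum())
        acc = hits / len(idx)
        prop_scores.append(acc)
        records.append({"role": "propensity", "candidate": repr(cand), "score": acc, "metric": "cv_accuracy"})
    best_prop = propensity_candidates[int(np.argmax(prop_scores))]

    # outcome: arm-wise CV, pooled squared error -> RMSE
    out_scores = []
    for cand in outcome_candidates:
        sse, n_scored = 0.0, 0
        for t in range(T):
            mask = np.flatnonzero(idx == t)
            kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
            for tr, te in kf.split(mask):
                est = clone(cand)
                est.fit(X[mask[tr]], y[mask[tr]])
                resid = est.predict(X[mask[te]]) - y[mask[te]]
                sse += float(resid @ resid)
                n_scored += len(te)
        rmse = float(np.sqrt(sse / n_scored))
        out_scores.append(rmse)
        records.append({"role": "outcome", "candidate": repr(cand), "score": rmse, "metric": "cv_rmse"})
    best_out = outcome_candidates[int(np.argmin(out_scores))]

    report = pd.DataFrame(records)
    prop_model = PropensityModel.fit(best_prop, train)
    out_model = OutcomeModel.fit(best_out, train)
    return prop_model, out_model, report


# ---------------------------------------------------------------------------
# score tables and policy values


def _clipped_propensity(prop_matrix: np.ndarray, clip_floor: float) -> np.ndarray:
    if (prop_matrix <= 0).any():
        warnings.warn(
            "nonpositive propensity estimates encountered; clipping at "
            f"{clip_floor}",
            RuntimeWarning,
            stacklevel=3,
        )
    return np.maximum(prop_matrix, clip_floor)


def score_table(
    data: ObservationalDataset,
    prop=None,
    out=None,
    method: str = "dr",
    clip_floor: float = 0.01,
) -> CounterfactualTable:
    """Build a counterfactual score table with the requested estimator.

    ``prop`` and ``out`` are objects following the ``PropensityModel`` /
    ``OutcomeModel`` contracts (aligned ``predict_proba`` / ``predict``).
    """
    if not 0.0 < clip_floor < 0.5:
        raise ValueError("clip_floor must lie in (0, 0.5)")
    n, T = data.n, len(data.treatment_set)
    obs = data.treatment_indices
    indicator = np.zeros((n, T))
    indicator[np.arange(n), obs] = 1.0

    if method in ("ipw", "dr"):
        if prop is None:
            raise ValueError(f"method {method!r} requires a propensity model")
        p = _clipped_propensity(np.asarray(prop.predict_proba(data.covariates), dtype=float), clip_floor)
    else:
        p = np.full((n, T), np.nan)
    if method in ("dm", "dr"):
        if out is None:
            raise ValueError(f"method {method!r} requires an outcome model")
        mu = np.asarray(out.predict(data.covariates), dtype=float)
        if not np.isfinite(mu).all():
            raise ValueError("outcome model produced non-finite predictions")
    else:
        mu = np.zeros((n, T))

    y = data.outcomes[:, None]
    if method == "ipw":
        psi = indicator * y / p
        p_store = p
    elif method == "dm":
        psi = mu.copy()
        p_store = np.full((n, T), np.nan)
    else:  # dr
        psi = mu + indicator * (y - mu) / p
        p_store = p
    return CounterfactualTable(
        psi=psi, propensity=p_store, mu=mu, method=method,
        clip_floor=clip_floor, treatment_set=data.treatment_set,
    )


def dr_score_table(
    data: ObservationalDataset, prop, out, clip_floor: float = 0.01
) -> CounterfactualTable:
    """Doubly robust (AIPW) score table; see module docstring for the formula."""
    return score_table(data, prop=prop, out=out, method="dr", clip_floor=clip_floor)


def _assignment_indices(assignments, treatment_set: TreatmentSet, n: int) -> np.ndarray:
    assignments = np.asarray(assignments)
    if assignments.shape != (n,):
        raise ValueError(f"expected {n} assignments, got shape {assignments.shape}")
    return treatment_set.indices_of(assignments.tolist())


def ipw_value(
    data: ObservationalDataset, assignments, prop, clip_floor: float = 0.01
) -> float:
    """Inverse-propensity-weighted value of a policy's assignments."""
    s = _assignment_indices(assignments, data.treatment_set, data.n)
    p = _clipped_propensity(
        np.asarray(prop.predict_proba(data.covariates), dtype=float), clip_floor
    )
    obs = data.treatment_indices
    p_obs = p[np.arange(data.n), obs]
    agree = (s == obs).astype(float)
    return float(np.mean(agree * data.outcomes / p_obs))


def dm_value(data: ObservationalDataset, assignments, out) -> float:
    """Direct-method value: mean of mu under the prescribed arms."""
    s = _assignment_indices(assignments, data.treatment_set, data.n)
    mu = np.asarray(out.predict(data.covariates), dtype=float)
    return float(np.mean(mu[np.arange(data.n), s]))


def dr_policy_value(table: CounterfactualTable, assignments) -> float:
    """Mean of the psi entry selected by the policy in each row."""
    s = _assignment_indices(assignments, table.treatment_set, table.n)
    return float(np.mean(table.psi[np.arange(table.n), s]))


def observed_policy(data: ObservationalDataset) -> np.ndarray:
    """The baseline 'policy in the data': each row's observed treatment."""
    return data.treatments.copy()


def _resolve_baseline(baseline, X: np.ndarray) -> np.ndarray:
    if callable(baseline):
        return np.asarray(baseline(X))
    if hasattr(baseline, "assign"):
        return np.asarray(baseline.assign(X))
    return np.asarray(baseline)


def dr_policy_advantage(
    table: CounterfactualTable, assignments, baseline, X: np.ndarray | None = None
) -> float:
    """Value difference of a policy over a baseline on the same score table.

    ``baseline`` may be an assignment vector, a callable ``X -> labels``, or
    an object with an ``assign(X)`` method.
    """
    base = _resolve_baseline(baseline, X)
    return dr_policy_value(table, assignments) - dr_policy_value(table, base)
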