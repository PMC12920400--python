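"""Policy scoring, cross-validated training, paired comparison, rankings.

Out-of-sample performance (OOSP) is the percentage of test individuals whose
prescribed treatment equals their realized optimal treatment; policy RMSE is
the root-mean-square regret of the attained outcome relative to the best
attainable one.  Both require the simulator's counterfactual side-car and so
apply only to synthetic data.  For real data, policies are compared by their
doubly robust value on held-out folds and by paired t tests across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from . import counterfactual as cf
from .mip import MIPConfig, train_pnn
from .network import (
    NetworkArchitecture,
    ObservationalDataset,
    PolicyNetwork,
    forward_policy,
)
from .simulate import SimulatedDataset

__all__ = [
    "PolicyEvaluation",
    "oosp",
    "policy_rmse",
    "cross_validate",
    "paired_policy_test",
    "pairwise_comparison",
    "feature_importance",
    "normalized_rank_table",
]


@dataclass
class PolicyEvaluation:
    """Evaluation record for one policy on one test set."""

    n_test: int
    policy_value: float | None = None
    oosp: float | None = None
    rmse: float | None = None
    per_fold_values: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.oosp is not None and not 0.0 <= self.oosp <= 100.0:
            raise ValueError("oosp must be a percentage in [0, 100]")


def _optimal_labels(sim: SimulatedDataset) -> np.ndarray:
    labels = np.asarray(sim.data.treatment_set.labels)
    return labels[sim.optimal_treatment]


def oosp(prescribed, sim: SimulatedDataset) -> float:
    """Percent of rows prescribed their realized optimal treatment."""
    prescribed = np.asarray(prescribed)
    if prescribed.shape != (sim.data.n,):
        raise ValueError("prescribed assignments must have one entry per row")
    return 100.0 * float(np.mean(prescribed == _optimal_labels(sim)))


def policy_rmse(prescribed, sim: SimulatedDataset) -> float:
    """Root-mean-square regret versus the best attainable outcome per row."""
    prescribed = np.asarray(prescribed)
    n = sim.data.n
    if prescribed.shape != (n,):
        raise ValueError("prescribed assignments must have one entry per row")
    s = sim.data.treatment_set.indices_of(prescribed.tolist())
    attained = sim.potential_outcomes[np.arange(n), s]
    best = sim.potential_outcomes.max(axis=1)
    return float(np.sqrt(np.mean((attained - best) ** 2)))


def _folds(data: ObservationalDataset, n_folds: int, seed: int):
    """Seed-deterministic disjoint folds; retries stratified when a plain
    split would lose an arm from a training part."""
    idx = data.treatment_indices

    def ok(splits):
        n_arms = len(data.treatment_set)
        return all(len(np.unique(idx[tr])) == n_arms for tr, _ in splits)

    plain = list(KFold(n_folds, shuffle=True, random_state=seed).split(data.covariates))
    if ok(plain):
        return plain
    if np.bincount(idx).min() >= n_folds:
        strat = list(
            StratifiedKFold(n_folds, shuffle=True, random_state=seed).split(
                data.covariates, idx
            )
        )
        if ok(strat):
            return strat
    raise ValueError(
        "could not build folds keeping every treatment arm in each training part"
    )


def cross_validate(
    data: ObservationalDataset,
    arch: NetworkArchitecture,
    cfg: MIPConfig,
    propensity_candidates: list,
    outcome_candidates: list,
    n_folds: int = 10,
    seed: int = 0,
    method: str = "dr",
    clip_floor: float = 0.01,
):
    """Train one network per fold and score it on the held-out part.

    Per fold: nuisance models are selected and fit on the training part
    only, the counterfactual table built from them drives the MIP, and the
    learned policy is valued on the held-out rows with held-out scores.
    Returns a list of ``(PolicyNetwork, PolicyEvaluation)`` pairs, one per
    fold.
    """
    results = []
    for fold_seed, (tr, te) in enumerate(_folds(data, n_folds, seed)):
        sub = ObservationalDataset(
            covariates=data.covariates[tr],
            treatments=data.treatments[tr],
            outcomes=data.outcomes[tr],
            direction=data.direction,
            treatment_set=data.treatment_set,
        )
        held = ObservationalDataset(
            covariates=data.covariates[te],
            treatments=data.treatments[te],
            outcomes=data.outcomes[te],
            direction=data.direction,
            treatment_set=data.treatment_set,
        )
        prop, out, _ = cf.fit_nuisance(
            sub,
            propensity_candidates,
            outcome_candidates,
            n_folds=min(n_folds, max(2, np.bincount(sub.treatment_indices).min())),
            seed=seed + fold_seed,
        )
        table = cf.score_table(sub, prop=prop, out=out, method=method, clip_floor=clip_floor)
        res = train_pnn(sub, table, arch, cfg)
        assignments = forward_policy(res.network, held.covariates)
        held_table = cf.score_table(
            held, prop=prop, out=out, method=method, clip_floor=clip_floor
        )
        value = cf.dr_policy_value(held_table, assignments)
        results.append(
            (res.network, PolicyEvaluation(n_test=held.n, policy_value=value))
        )
    return results


def paired_policy_test(values_a, values_b):
    """Two-sided paired t test on per-unit value differences.

    Returns ``(mean difference, t statistic, p value)`` with the difference
    taken as a - b.  Zero-variance differences are handled explicitly: all
    zeros gives (0, 0, 1); constant nonzero gives an infinite statistic and
    p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    bvals = np.asarray(values_b, dtype=float)
    if a.shape != bvals.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length paired samples of size >= 2")
    diff = a - bvals
    mean = float(diff.mean())
    if np.allclose(diff, diff[0]):
        if mean == 0.0:
            return 0.0, 0.0, 1.0
        return mean, float(np.sign(mean) * np.inf), 0.0
    t, p = stats.ttest_rel(a, bvals)
    return mean, float(t), float(p)


def pairwise_comparison(values_by_model: dict):
    """Pairwise mean differences and paired-test p values between models.

    ``values_by_model`` maps a model name to its per-fold value vector.
    Returns two square DataFrames indexed by model name: mean differences
    (row minus column) and two-sided p values.
    """
    names = list(values_by_model)
    k = len(names)
    diffs = np.zeros((k, k))
    pvals = np.ones((k, k))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                continue
            d, _, p = paired_policy_test(values_by_model[a], values_by_model[b])
            diffs[i, j] = d
            pvals[i, j] = p
    return (
        pd.DataFrame(diffs, index=names, columns=names),
        pd.DataFrame(pvals, index=names, columns=names),
    )


def feature_importance(net: PolicyNetwork) -> np.ndarray:
    """Mean absolute input weight per feature across hidden units."""
    return np.abs(net.parameters.input_weights).mean(axis=1)


def _fold_ranks(scores: np.ndarray) -> np.ndarray:
    """Rank 1 = most important; ties share the mean position; zero-score
    features all take the worst rank."""
    scores = np.asarray(scores, dtype=float)
    F = len(scores)
    ranks = np.full(F, float(F))
    nz = np.flatnonzero(scores != 0.0)
    if len(nz):
        ranks[nz] = stats.rankdata(-scores[nz], method="average")
    return ranks


def normalized_rank_table(per_fold_scores, binarized_groups: dict | None = None):
    """Fold-averaged, normalized feature importance in [0, 1].

    Per fold, features are ranked descending by score; ranks are averaged
    across folds; optionally each named group of (binarized) columns is
    collapsed to its best (minimum) member rank; averaged ranks are mapped
    to [0, 1] via (rank - 1) / (F_eff - 1) and reported as 1 minus that, so
    larger means more important.  A single effective feature reports 1.
    """
    folds = [np.asarray(s, dtype=float) for s in per_fold_scores]
    if not folds:
        raise ValueError("need at least one fold of scores")
    F = len(folds[0])
    if any(len(s) != F for s in folds):
        raise ValueError("all folds must score the same features")
    avg = np.mean([_fold_ranks(s) for s in folds], axis=0)
    if binarized_groups:
        names = list(binarized_groups)
        avg = np.array([np.min(avg[np.asarray(binarized_groups[g])]) for g in names])
    else:
        names = list(range(F))
    F_eff = len(avg)
    if F_eff == 1:
        reported = np.array([1.0])
    else:
        reported = 1.0 - np.clip((avg - 1.0) / (F_eff - 1.0), 0.0, 1.0)
    return pd.Series(reported, index=names, name="importance")
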