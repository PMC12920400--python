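"""Mixed-integer programming training of 0-1 policy networks.

The training problem selects network weights, biases, and the per-row unit
activations jointly so that the policy implied by the network maximizes the
mean counterfactual score of the treatments it assigns:

    max (1/n) sum_i sum_t h[i,t] * psi[i,t]  -  l0 * #nonzero weights
                                             -  l1 * sum |weights|

subject to big-M indicator constraints tying each hidden activation
h[i,k,l] in {0,1} to the sign of its pre-activation, exact linearizations
z = alpha * h_prev of the bilinear products appearing from the second layer
on, and a one-treatment constraint sum_t h[i,t] = 1 per row.  The model is
solved with the HiGHS branch-and-bound solver via ``scipy.optimize.milp``.

Margins: a unit is forced *on* when its pre-activation is >= epsilon and
*off* when it is <= -epsilon/2.  The small negative off-margin keeps solver
solutions away from the pre-activation value 0, where the inference-time
indicator sigma(0) = 1 would disagree with a solver's h = 0; with it, the
solver's activations are reproduced exactly by the forward pass on the
training rows.  The output layer keeps the plain (>= epsilon / <= 0)
disjunction since inference there is an argmax, which is insensitive to the
boundary.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .counterfactual import CounterfactualTable, _resolve_baseline
from .network import (
    NetworkArchitecture,
    NetworkParameters,
    ObservationalDataset,
    PolicyNetwork,
    forward_hidden,
    forward_policy,
    forward_scores,
)

__all__ = ["MIPConfig", "SolveResult", "build_mip", "train_pnn", "brute_force_train"]


@dataclass(frozen=True)
class MIPConfig:
    """Formulation constants and solver settings.

    ``big_M`` of None selects data-driven per-layer constants: the input
    layer uses an upper bound on |alpha^T x + beta| from the weight bounds
    and the training covariate ranges; deeper layers use K * max|alpha| +
    max|beta| + 1.  ``integral_weights`` restricts weights and biases to the
    integer grid inside ``weight_bounds`` (used for exhaustive-oracle
    comparisons).
    """

    big_M: float | None = None
    epsilon: float = 1e-4
    weight_bounds: tuple = (-1.0, 1.0)
    l0_penalty: float = 0.0
    l1_penalty: float = 0.0
    time_limit_seconds: float = 600.0
    mip_gap_tolerance: float = 1e-4
    seed: int = 0
    backend: str = "highs"
    integral_weights: bool = False
    symmetry_breaking: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.weight_bounds
        if not lo < hi:
            raise ValueError("weight_bounds must satisfy lower < upper")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.big_M is not None and self.epsilon >= self.big_M:
            raise ValueError("epsilon must be much smaller than big_M")
        if self.l0_penalty < 0 or self.l1_penalty < 0:
            raise ValueError("regularization penalties must be nonnegative")
        if self.time_limit_seconds <= 0:
            raise ValueError("time_limit_seconds must be positive")


@dataclass
class SolveResult:
    """Outcome of one training solve."""

    network: PolicyNetwork
    objective_value: float
    best_bound: float
    gap: float
    status: str  # optimal | feasible_time_limit | infeasible | error
    wall_time: float
    train_hidden: list  # [(n, K)] binary activations per hidden layer
    train_output: np.ndarray  # (n, |T|) one-hot output


class _Builder:
    """Incremental sparse constraint-matrix assembly."""

    def __init__(self) -> None:
        self.n_vars = 0
        self.lb_var: list[float] = []
        self.ub_var: list[float] = []
        self.integrality: list[int] = []
        self.rows: list[int] = []
        self.cols: list[int] = []
        self.vals: list[float] = []
        self.lb_con: list[float] = []
        self.ub_con: list[float] = []
        self.obj: dict[int, float] = {}

    def add_vars(self, count: int, lb: float, ub: float, integer: bool) -> int:
        start = self.n_vars
        self.n_vars += count
        self.lb_var.extend([lb] * count)
        self.ub_var.extend([ub] * count)
        self.integrality.extend([1 if integer else 0] * count)
        return start

    def add_constraint(self, idx, coef, lb: float, ub: float) -> None:
        row = len(self.lb_con)
        self.rows.extend([row] * len(idx))
        self.cols.extend(idx)
        self.vals.extend(coef)
        self.lb_con.append(lb)
        self.ub_con.append(ub)

    def set_objective(self, idx: int, coef: float) -> None:
        self.obj[idx] = self.obj.get(idx, 0.0) + coef

    def matrix(self) -> sparse.csr_matrix:
        return sparse.coo_matrix(
            (self.vals, (self.rows, self.cols)),
            shape=(len(self.lb_con), self.n_vars),
        ).tocsr()


@dataclass
class MIPModel:
    """Abstract handle for a built (unsolved) training MIP."""

    data: ObservationalDataset
    table: CounterfactualTable
    arch: NetworkArchitecture
    cfg: MIPConfig
    c_max: np.ndarray  # objective coefficients (maximization sense)
    A: sparse.csr_matrix
    lb_con: np.ndarray
    ub_con: np.ndarray
    lb_var: np.ndarray
    ub_var: np.ndarray
    integrality: np.ndarray
    index: dict = field(default_factory=dict)
    baseline_constant: float = 0.0

    @property
    def n_variables(self) -> int:
        return self.A.shape[1]

    @property
    def n_constraints(self) -> int:
        return self.A.shape[0]


def signed_scores(table: CounterfactualTable, direction: str) -> np.ndarray:
    """psi-tilde: scores negated for minimize-direction outcomes so every
    optimizer maximizes."""
    return table.psi if direction == "maximize" else -table.psi


def build_mip(
    data: ObservationalDataset,
    table: CounterfactualTable,
    arch: NetworkArchitecture,
    cfg: MIPConfig,
    baseline=None,
) -> MIPModel:
    """Assemble the training MIP; see the module docstring for the model."""
    n, F, K, L = data.n, arch.n_features, arch.width, arch.n_hidden_layers
    T = arch.n_treatments
    if arch.n_features != data.n_features:
        raise ValueError("architecture feature count does not match the data")
    if table.n != n or table.treatment_set.labels != data.treatment_set.labels:
        raise ValueError("counterfactual table rows/treatments do not align with the data")
    X = data.covariates
    lo, hi = cfg.weight_bounds
    a_max = max(abs(lo), abs(hi))
    eps = cfg.epsilon
    delta = eps / 2.0  # off-margin; see module docstring
    if cfg.big_M is not None:
        M_mid = cfg.big_M
        M_row = np.full(n, cfg.big_M)
    else:
        # per-row pre-activation bound |alpha^T x_i + beta| <= a_max(sum_d
        # |x_id| + 1); the +1 slack keeps the epsilon disjunction strict
        M_row = a_max * (np.abs(X).sum(axis=1) + 1.0) + 1.0
        M_mid = K * a_max + a_max + 1.0
    if eps >= min(float(M_row.min()), M_mid):
        raise ValueError("epsilon must be smaller than the big-M constants")

    b = _Builder()
    intw = cfg.integral_weights
    ix: dict = {}
    ix["w0"] = b.add_vars(F * K, lo, hi, intw)  # w0[d,k] -> + d*K + k
    ix["wh"] = [b.add_vars(K * K, lo, hi, intw) for _ in range(L - 1)]
    ix["wL"] = b.add_vars(K * T, lo, hi, intw)  # wL[k,t] -> + k*T + t
    ix["b"] = [b.add_vars(K, lo, hi, intw) for _ in range(L)]
    ix["bL"] = b.add_vars(T, lo, hi, intw)
    ix["h"] = [b.add_vars(n * K, 0.0, 1.0, True) for _ in range(L)]  # h[l][i,k]
    ix["hL"] = b.add_vars(n * T, 0.0, 1.0, True)  # hL[i,t]
    ix["z"] = [b.add_vars(n * K * K, -a_max, a_max, False) for _ in range(L - 1)]
    ix["zL"] = b.add_vars(n * K * T, -a_max, a_max, False)

    def w0(d, k):
        return ix["w0"] + d * K + k

    def wh(l, kp, k):  # layer l in 1..L-1
        return ix["wh"][l - 1] + kp * K + k

    def wL(k, t):
        return ix["wL"] + k * T + t

    def bias(l, k):
        return ix["b"][l] + k

    def bL(t):
        return ix["bL"] + t

    def h(l, i, k):
        return ix["h"][l] + i * K + k

    def hL(i, t):
        return ix["hL"] + i * T + t

    def z(l, i, kp, k):
        return ix["z"][l - 1] + (i * K + kp) * K + k

    def zL(i, kp, t):
        return ix["zL"] + (i * K + kp) * T + t

    inf = np.inf
    # input layer indicator constraints
    for i in range(n):
        xi = X[i]
        Mi = float(M_row[i])
        for k in range(K):
            idx = [w0(d, k) for d in range(F)] + [bias(0, k), h(0, i, k)]
            coef = list(xi) + [1.0, -(Mi + delta)]
            b.add_constraint(idx, coef, -inf, -delta)  # off: preact <= -delta
            coef_on = list(xi) + [1.0, -(Mi + eps)]
            b.add_constraint(idx, coef_on, -Mi, inf)  # on: preact >= eps

    # deeper hidden layers: indicator + bilinear linearization
    for l in range(1, L):
        for i in range(n):
            for k in range(K):
                idx = [z(l, i, kp, k) for kp in range(K)] + [bias(l, k), h(l, i, k)]
                b.add_constraint(idx, [1.0] * K + [1.0, -(M_mid + delta)], -inf, -delta)
                b.add_constraint(idx, [1.0] * K + [1.0, -(M_mid + eps)], -M_mid, inf)
            for kp in range(K):
                hp = h(l - 1, i, kp)
                for k in range(K):
                    zv, wv = z(l, i, kp, k), wh(l, kp, k)
                    b.add_constraint([zv, wv, hp], [1.0, -1.0, a_max], -inf, a_max)
                    b.add_constraint([zv, wv, hp], [1.0, -1.0, -a_max], -a_max, inf)
                    b.add_constraint([zv, hp], [1.0, -a_max], -inf, 0.0)
                    b.add_constraint([zv, hp], [1.0, a_max], 0.0, inf)

    # output layer: binary one-hot scores + bilinear linearization
    for i in range(n):
        for t in range(T):
            idx = [zL(i, kp, t) for kp in range(K)] + [bL(t), hL(i, t)]
            b.add_constraint(idx, [1.0] * K + [1.0, -M_mid], -inf, 0.0)
            b.add_constraint(idx, [1.0] * K + [1.0, -(M_mid + eps)], -M_mid, inf)
        for kp in range(K):
            hp = h(L - 1, i, kp)
            for t in range(T):
                zv, wv = zL(i, kp, t), wL(kp, t)
                b.add_constraint([zv, wv, hp], [1.0, -1.0, a_max], -inf, a_max)
                b.add_constraint([zv, wv, hp], [1.0, -1.0, -a_max], -a_max, inf)
                b.add_constraint([zv, hp], [1.0, -a_max], -inf, 0.0)
                b.add_constraint([zv, hp], [1.0, a_max], 0.0, inf)
        # exactly one treatment per row
        b.add_constraint([hL(i, t) for t in range(T)], [1.0] * T, 1.0, 1.0)

    if cfg.symmetry_breaking and K > 1:
        # hidden units within a layer are interchangeable; ordering their
        # biases removes the K! duplication without touching the optimum
        for l in range(L):
            for k in range(K - 1):
                b.add_constraint([bias(l, k), bias(l, k + 1)], [1.0, -1.0], -inf, 0.0)

    # objective: policy value of the selected scores
    psi = signed_scores(table, data.direction)
    for i in range(n):
        for t in range(T):
            b.set_objective(hL(i, t), psi[i, t] / n)

    weight_vars = (
        [w0(d, k) for d in range(F) for k in range(K)]
        + [wh(l, kp, k) for l in range(1, L) for kp in range(K) for k in range(K)]
        + [wL(k, t) for k in range(K) for t in range(T)]
    )
    if cfg.l0_penalty > 0:
        ix["u"] = b.add_vars(len(weight_vars), 0.0, 1.0, True)
        for j, wv in enumerate(weight_vars):
            uv = ix["u"] + j
            b.add_constraint([wv, uv], [1.0, -hi], -inf, 0.0)  # w <= hi*u
            b.add_constraint([wv, uv], [1.0, -lo], 0.0, inf)  # w >= lo*u
            b.set_objective(uv, -cfg.l0_penalty)
    if cfg.l1_penalty > 0:
        ix["l1_pos"] = b.add_vars(len(weight_vars), 0.0, a_max, False)
        ix["l1_neg"] = b.add_vars(len(weight_vars), 0.0, a_max, False)
        for j, wv in enumerate(weight_vars):
            pv, mv = ix["l1_pos"] + j, ix["l1_neg"] + j
            b.add_constraint([wv, pv, mv], [1.0, -1.0, 1.0], 0.0, 0.0)
            b.set_objective(pv, -cfg.l1_penalty)
            b.set_objective(mv, -cfg.l1_penalty)

    baseline_constant = 0.0
    if baseline is not None:
        base = _resolve_baseline(baseline, X)
        bidx = data.treatment_set.indices_of(np.asarray(base).tolist())
        baseline_constant = float(np.mean(psi[np.arange(n), bidx]))

    c_max = np.zeros(b.n_vars)
    for j, v in b.obj.items():
        c_max[j] = v
    return MIPModel(
        data=data,
        table=table,
        arch=arch,
        cfg=cfg,
        c_max=c_max,
        A=b.matrix(),
        lb_con=np.array(b.lb_con),
        ub_con=np.array(b.ub_con),
        lb_var=np.array(b.lb_var),
        ub_var=np.array(b.ub_var),
        integrality=np.array(b.integrality),
        index=ix,
        baseline_constant=baseline_constant,
    )


def _extract_network(model: MIPModel, x: np.ndarray) -> PolicyNetwork:
    arch, cfg, ix = model.arch, model.cfg, model.index
    F, K, L, T = arch.n_features, arch.width, arch.n_hidden_layers, arch.n_treatments
    lo, hi = cfg.weight_bounds

    def grab(start, count):
        vals = np.asarray(x[start : start + count], dtype=float)
        if cfg.integral_weights:
            vals = np.round(vals)
        return np.clip(vals, lo, hi)

    params = NetworkParameters(
        input_weights=grab(ix["w0"], F * K).reshape(F, K),
        hidden_weights=[grab(s, K * K).reshape(K, K) for s in ix["wh"]],
        output_weights=grab(ix["wL"], K * T).reshape(K, T),
        hidden_biases=[grab(s, K) for s in ix["b"]],
        output_biases=grab(ix["bL"], T),
        weight_bounds=(lo, hi),
    )
    return PolicyNetwork(
        architecture=arch,
        parameters=params,
        activation_threshold=cfg.epsilon,
        metadata={
            "objective": model.table.method,
            "seed": cfg.seed,
            "backend": cfg.backend,
        },
    )


def train_pnn(
    data: ObservationalDataset,
    table: CounterfactualTable,
    arch: NetworkArchitecture,
    cfg: MIPConfig,
    baseline=None,
) -> SolveResult:
    """Build and solve the training MIP, returning the incumbent network.

    Solves to proven optimality within ``mip_gap_tolerance`` or returns the
    best incumbent at the time limit together with its optimality gap.
    """
    model = build_mip(data, table, arch, cfg, baseline=baseline)
    t0 = time.perf_counter()
    res = milp(
        c=-model.c_max,  # HiGHS minimizes
        constraints=[LinearConstraint(model.A, model.lb_con, model.ub_con)],
        integrality=model.integrality,
        bounds=Bounds(model.lb_var, model.ub_var),
        options={
            "time_limit": cfg.time_limit_seconds,
            "mip_rel_gap": cfg.mip_gap_tolerance,
            "presolve": True,
        },
    )
    wall = time.perf_counter() - t0
    if res.status == 2:
        raise RuntimeError(
            "training MIP is infeasible; a constant policy is always feasible, "
            "so check the big-M / epsilon configuration (epsilon may exceed big_M)"
        )
    if res.x is None:
        raise RuntimeError(
            "no incumbent found within the time limit; increase "
            "time_limit_seconds or reduce the network width"
        )
    x = np.asarray(res.x, dtype=float)
    net = _extract_network(model, x)
    objective = float(model.c_max @ x) - model.baseline_constant

    dual = getattr(res, "mip_dual_bound", None)
    bound = -float(dual) - model.baseline_constant if dual is not None else objective
    gap = abs(objective - bound) / max(abs(objective), 1e-10)
    status = "optimal" if res.status == 0 else "feasible_time_limit"
    if status == "optimal":
        gap = min(gap, cfg.mip_gap_tolerance)

    n, K, L, T = data.n, arch.width, arch.n_hidden_layers, arch.n_treatments
    ix = model.index
    hidden = [
        (x[ix["h"][l] : ix["h"][l] + n * K].reshape(n, K) > 0.5).astype(np.int8)
        for l in range(L)
    ]
    output = (x[ix["hL"] : ix["hL"] + n * T].reshape(n, T) > 0.5).astype(np.int8)
    net.metadata.update(
        {"status": status, "objective_value": objective, "gap": gap, "wall_time": wall}
    )
    return SolveResult(
        network=net,
        objective_value=objective,
        best_bound=bound,
        gap=gap,
        status=status,
        wall_time=wall,
        train_hidden=hidden,
        train_output=output,
    )


def brute_force_train(
    data: ObservationalDataset,
    table: CounterfactualTable,
    arch: NetworkArchitecture,
    weight_grid,
    cfg: MIPConfig,
    enumeration_cap: int = 10**6,
):
    """Exhaustive oracle: enumerate every weight/bias assignment on a grid.

    Evaluates the (regularized) policy-value objective through the inference
    forward pass and returns ``(best NetworkParameters, best objective)``.
    Independent of the MIP path; intended for validating it on tiny
    instances.
    """
    grid = tuple(float(g) for g in weight_grid)
    F, K, L, T = arch.n_features, arch.width, arch.n_hidden_layers, arch.n_treatments
    n_params = F * K + (L - 1) * K * K + K * T + L * K + T
    total = len(grid) ** n_params
    if total > enumeration_cap:
        raise ValueError(
            f"enumeration size {total} exceeds the cap {enumeration_cap}"
        )
    psi = signed_scores(table, data.direction)
    X = data.covariates
    rows = np.arange(data.n)
    best_obj, best_params = -np.inf, None
    for combo in itertools.product(grid, repeat=n_params):
        vals = np.array(combo)
        pos = 0

        def take(count):
            nonlocal pos
            out = vals[pos : pos + count]
            pos += count
            return out

        params = NetworkParameters(
            input_weights=take(F * K).reshape(F, K),
            hidden_weights=[take(K * K).reshape(K, K) for _ in range(L - 1)],
            output_weights=take(K * T).reshape(K, T),
            hidden_biases=[take(K) for _ in range(L)],
            output_biases=take(T),
            weight_bounds=cfg.weight_bounds,
        )
        net = PolicyNetwork(architecture=arch, parameters=params,
                            activation_threshold=cfg.epsilon)
        assigned = arch.treatments.indices_of(forward_policy(net, X).tolist())
        obj = float(np.mean(psi[rows, assigned]))
        if cfg.l0_penalty > 0 or cfg.l1_penalty > 0:
            w_all = np.concatenate(
                [params.input_weights.ravel()]
                + [w.ravel() for w in params.hidden_weights]
                + [params.output_weights.ravel()]
            )
            obj -= cfg.l0_penalty * int(np.count_nonzero(w_all))
            obj -= cfg.l1_penalty * float(np.abs(w_all).sum())
        if obj > best_obj:
            best_obj, best_params = obj, params
    return best_params, best_obj
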