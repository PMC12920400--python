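import numpy as np
import pytest

from pnn import (
    CounterfactualTable,
    NetworkArchitecture,
    NetworkParameters,
    ObservationalDataset,
    PolicyNetwork,
    TreatmentSet,
)


@pytest.fixture
def binary_treatments():
    return TreatmentSet((0, 1))


@pytest.fixture
def step_net(binary_treatments):
    """F=1, K=1 net: hidden unit fires iff x >= 0.5; output prefers arm 1
    when the unit fires and arm 0 otherwise."""
    arch = NetworkArchitecture(1, 1, 1, binary_treatments)
    params = NetworkParameters(
        input_weights=[[1.0]],
        hidden_weights=[],
        output_weights=[[-1.0, 1.0]],
        hidden_biases=[[-0.5]],
        output_biases=[0.5, -0.5],
    )
    return PolicyNetwork(arch, params)


def make_net(arch, rng=None, scale=0.5):
    """Random network within default weight bounds."""
    rng = rng or np.random.default_rng(0)
    F, K, L, T = arch.n_features, arch.width, arch.n_hidden_layers, arch.n_treatments
    u = lambda *shape: rng.uniform(-scale, scale, shape)
    params = NetworkParameters(
        input_weights=u(F, K),
        hidden_weights=[u(K, K) for _ in range(L - 1)],
        output_weights=u(K, T),
        hidden_biases=[u(K) for _ in range(L)],
        output_biases=u(T),
    )
    return PolicyNetwork(arch, params)


def make_dataset(n=8, F=2, seed=0, direction="maximize"):
    rng = np.random.default_rng(seed)
    return ObservationalDataset(
        covariates=rng.standard_normal((n, F)),
        treatments=rng.integers(0, 2, n),
        outcomes=rng.standard_normal(n),
        direction=direction,
        treatment_set=TreatmentSet((0, 1)),
    )


def make_table(psi, clip_floor=0.01, method="dr"):
    psi = np.asarray(psi, dtype=float)
    n, T = psi.shape
    return CounterfactualTable(
        psi=psi,
        propensity=np.full((n, T), 0.5),
        mu=np.zeros((n, T)),
        method=method,
        clip_floor=clip_floor,
        treatment_set=TreatmentSet(tuple(range(T))),
    )
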