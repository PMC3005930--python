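import numpy as np
import pytest

import fdanet as fn


@pytest.fixture
def linear_series():
    """y = 2t + 1 on 5 points — a cubic spline must reproduce the line."""
    t = np.linspace(0.0, 4.0, 5)
    return fn.ExpressionSeries("linear", ("g1",), t, (2 * t + 1)[None, :])


@pytest.fixture
def sin_series():
    """sin(t) sampled at 8 knots on [0, pi]."""
    t = np.linspace(0.0, np.pi, 8)
    return fn.ExpressionSeries("sin", ("g1",), t, np.sin(t)[None, :])


@pytest.fixture
def mutual_repression_model():
    """Two genes repressing each other; logistic sigmoid."""
    genes = ("a", "b")
    params = {
        "a": fn.GeneModelParams("a", 10.0, {"b": -0.15}, 1.0, 0.8),
        "b": fn.GeneModelParams("b", 12.0, {"a": -0.1}, 0.5, 1.0),
    }
    return fn.NetworkModel(genes, params, "logistic")


@pytest.fixture(scope="session")
def benchmark():
    """Packaged seeded recovery benchmark: sparse 5-gene, 20 noiseless series."""
    spec = fn.SyntheticSpec(seed=1)
    series, model, gold = fn.generate_benchmark(spec)
    return spec, series, model, gold


@pytest.fixture(scope="session")
def benchmark_splines(benchmark):
    _, series, _, _ = benchmark
    return [fn.fit_spline(s) for s in series]


@pytest.fixture(scope="session")
def benchmark_fit(benchmark):
    """Shared 50-start fit of the packaged benchmark (irma_gnw preset)."""
    _, series, _, _ = benchmark
    mod = fn.GeneNetworkModel(series, preset="irma_gnw")
    return mod, mod.fit(n_starts=50, seed=1)
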