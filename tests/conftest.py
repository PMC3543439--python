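import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from meltquant import (AssayConfig, MeltModelParams, TruthEntry, TruthTable,
                       simulate_plate)
from meltquant.simulate import default_cpg_pct

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def apc_cfg() -> AssayConfig:
    """Default APC-like assay: melt window 74-80 °C."""
    return AssayConfig.default("APC")


@pytest.fixture(scope="session")
def noiseless_params() -> MeltModelParams:
    return MeltModelParams()


def make_truth(ms, het=None, n_cpg=7, prefix="S"):
    """Truth table from a list of methylated fractions (het: list of bools)."""
    het = het or [False] * len(ms)
    entries = []
    for i, (m, h) in enumerate(zip(ms, het)):
        comps = ((-2.0, 0.5), (2.0, 0.5)) if h else None
        entries.append(TruthEntry(f"{prefix}{i + 1:03d}", m, components=comps,
                                  cpg_pct=default_cpg_pct(m, n_cpg, h)))
    return TruthTable(entries)


@pytest.fixture()
def noiseless_plate(noiseless_params):
    """Six standard levels in triplicate plus four known samples, no noise."""
    truth = make_truth([0.05, 0.33, 0.66, 0.95])
    curves, sheet = simulate_plate(samples=truth, params=noiseless_params, seed=0)
    return curves, sheet, truth


def lagrange_eval(x_nodes, y_nodes, x):
    """Independent Lagrange interpolation oracle: explicit product formula."""
    x_nodes = np.asarray(x_nodes, float)
    y_nodes = np.asarray(y_nodes, float)
    x = np.atleast_1d(np.asarray(x, float))
    out = np.zeros_like(x)
    for i, (xi, yi) in enumerate(zip(x_nodes, y_nodes)):
        basis = np.ones_like(x)
        for j, xj in enumerate(x_nodes):
            if j != i:
                basis *= (x - xj) / (xi - xj)
        out += yi * basis
    return out
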