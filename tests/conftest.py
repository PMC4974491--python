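"""Shared fixtures: small hand-built matrices and one session-scoped run of
the full benchmark pipeline (simulate -> preprocess -> three per-condition
networks) reused by the heavier integration tests."""

import numpy as np
import pandas as pd
import pytest

from ascnet import (
    ExpressionMatrix,
    build_network,
    filter_undetected,
    quantile_normalize,
    recovery_benchmark_config,
    sample_id,
    simulate_timecourse,
)


def make_matrix(values: np.ndarray, conditions, timepoints, donors) -> ExpressionMatrix:
    """ExpressionMatrix from an array laid out condition-major, then
    timepoint, then donor (the generator's column order)."""
    cols = [
        sample_id(c, t, d) for c in conditions for t in timepoints for d in donors
    ]
    probes = [f"probe_{i:05d}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=cols))


@pytest.fixture
def small_matrix():
    """12 probes x (2 conditions x 3 timepoints x 2 donors) of seeded noise."""
    rng = np.random.default_rng(5)
    return make_matrix(
        rng.normal(8, 1, (12, 12)), ["none", "ifn_alpha"], [0.0, 6.0, 24.0], ["1", "2"]
    )


@pytest.fixture(scope="session")
def benchmark_run():
    """Benchmark simulation and its three per-condition networks (seed 0)."""
    cfg = recovery_benchmark_config(seed=0)
    x, det, truth = simulate_timecourse(cfg)
    xq = quantile_normalize(filter_undetected(x, det))
    nets = {c: build_network(xq, c) for c in cfg.conditions}
    return {"config": cfg, "expr": xq, "truth": truth, "networks": nets}
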