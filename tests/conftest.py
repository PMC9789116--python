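"""Shared fixtures.

The expensive objects — ten seeded replicate fits of the default scenario,
and the labeled strong-biology scenario for control identification — are
session-scoped so every test that scores the same study conditions reuses
one computation.
"""

import warnings

import numpy as np
import pytest

import ruvnb
from ruvnb.io import build_replicate_matrix, filter_by_cpm

warnings.filterwarnings("ignore", category=UserWarning)

N_REPLICATE_SEEDS = 10


@pytest.fixture(scope="session")
def default_replicates():
    """Ten seeded replicates of the default scenario, CPM-filtered and
    fitted with the true control set (k = 3: depth + storage + kit)."""
    out = []
    for seed in range(1, N_REPLICATE_SEEDS + 1):
        cm, truth = ruvnb.default_scenario(seed=seed)
        cmf = filter_by_cpm(cm)
        M = build_replicate_matrix(truth.metadata, cmf.sample_ids)
        controls = truth.control_set().restrict(cmf)
        fit = ruvnb.fit_ruv3nb(cmf, M, controls, k=3, seed=seed)
        out.append({"cm": cmf, "truth": truth, "M": M, "fit": fit, "seed": seed})
    return out


@pytest.fixture(scope="session")
def labeled_scenario():
    """Strong-biology scenario with labeled beta=0 taxa and a spiked/unspiked
    sample partition, CPM-filtered, for control-identification scoring."""
    cm, truth = ruvnb.simulate_experiment(
        seed=21,
        T=800,
        n_controls=320,
        n_spikes=8,
        bio_floor=1.2,
        sparsity_target=0.6,
        zeta_scale=4.0,  # heavy-tailed abundance spectrum: realistic depth
        spike_fraction=0.5,
    )
    cmf = filter_by_cpm(cm)
    return {"cm": cmf, "truth": truth}


@pytest.fixture()
def small_counts():
    """A tiny deterministic count matrix for interface tests."""
    rng = np.random.default_rng(42)
    counts = rng.poisson(20, size=(12, 6))
    counts[0] = [1, 2, 0, 5, 10, 0]
    return ruvnb.CountMatrix(
        [f"t{i}" for i in range(12)], [f"s{j}" for j in range(6)], counts
    )


def canonical_corr(X, Y):
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    Qx, _ = np.linalg.qr(Xc)
    Qy, _ = np.linalg.qr(Yc)
    return np.linalg.svd(Qx.T @ Qy, compute_uv=False)
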