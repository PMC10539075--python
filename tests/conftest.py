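"""Shared fixtures.

The two heavyweight session fixtures run the simulation study once at
reduced (desk) scale and are shared by every test that inspects empirical
rejection rates or coefficient distributions:

* ``null_experiments`` -- the null calibration (h_d2 = h_i2 = 0) at two
  masked-set sizes, 1000 replicates each;
* ``power_grid`` -- the k = 10 power surface over nu x n_missing,
  500 replicates per cell.

Replicate counts are the package's desk-scale defaults; every assertion
that consumes these fixtures computes its Monte-Carlo standard errors from
the replicate counts actually used.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from wip import SimConfig, run_experiment

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

NULL_REPS = 1000
GRID_REPS = 500
NU_GRID = (0.0, 0.3, 0.5, 0.8, 1.0)
NM_GRID = (1000, 2500, 5000)

#: reference rejection rates at alpha = 0.05 for k = 10 (method, nu, n_missing)
PRINTED_POWER = {
    ("LR", 0.0): 0.1590,
    ("IP", 0.0, 5000): 0.1203,
    ("LR", 1.0): 0.2546,
    ("WIP", 1.0, 5000): 0.3667,
}


@pytest.fixture(scope="session")
def null_experiments():
    out = {}
    for n_m, seed in ((1000, 91_001), (5000, 91_005)):
        cfg = SimConfig.desk(nu=0.0, h_d2=0.0, h_i2=0.0, n_missing=n_m, reps=NULL_REPS)
        out[n_m] = run_experiment(cfg, seed=seed)
    return out


@pytest.fixture(scope="session")
def power_grid():
    out = {}
    for i, nu in enumerate(NU_GRID):
        for j, n_m in enumerate(NM_GRID):
            cfg = SimConfig.desk(
                nu=nu, h_d2=1e-4, h_i2=1e-3, k=10, n_missing=n_m, reps=GRID_REPS
            )
            out[(nu, n_m)] = run_experiment(cfg, seed=77_000 + 10 * i + j)
    return out


def rate_at(result, method: str, alpha: float = 0.05) -> tuple[float, float]:
    """(rejection rate, binomial SE) for one method of a SimResult."""
    p = result.pvalues[method]
    p = p[np.isfinite(p)]
    r = float(np.mean(p < alpha))
    return r, float(np.sqrt(r * (1 - r) / p.size))
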