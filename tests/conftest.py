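"""Shared fixtures: small file-backed survey tables and fitted landscapes.

Heavy fixtures are session-scoped so the recovery checks and the
per-module tests share one generated landscape and one fitted pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import evdkit
from evdkit.dataset import RunConfig


@pytest.fixture()
def toy_tables(tmp_path):
    """Five sites, three species, three variables, written as CSV files."""
    env = pd.DataFrame(
        {
            "site_id": ["A", "B", "C", "D", "E"],
            "x": [0.0, 1.0, 2.0, 3.0, 4.0],
            "y": [0.0, 0.5, 1.0, 1.5, 2.0],
            "tp": [0.1, 0.2, 0.3, 0.4, 0.5],
            "ph": [6.5, 7.0, 7.5, 8.0, 8.5],
            "qhei": [80.0, 70.0, 60.0, 50.0, 40.0],
        }
    )
    occ = pd.DataFrame(
        {
            "site_id": ["A", "B", "C", "D", "E"],
            "sp1": [1, 1, 0, 0, 1],
            "sp2": [0, 1, 1, 1, 0],
            "sp3": [1, 0, 1, 0, 1],
        }
    )
    env_path, occ_path, ref_path = tmp_path / "env.csv", tmp_path / "occ.csv", tmp_path / "ref.txt"
    env.to_csv(env_path, index=False)
    occ.to_csv(occ_path, index=False)
    ref_path.write_text("A\nB\n")
    roles = {"tp": "stressor_increase", "ph": "stressor_both", "qhei": "stressor_decrease"}
    return {"env": env_path, "occ": occ_path, "reference": ref_path, "roles": roles}


@pytest.fixture(scope="session")
def small_landscape():
    spec = evdkit.demo_spec(n_sites=600, n_species=15, n_reference=10, seed=3)
    return evdkit.generate(spec)


@pytest.fixture(scope="session")
def small_config():
    return RunConfig(sweep_points=301)


@pytest.fixture(scope="session")
def small_result(small_landscape, small_config):
    return evdkit.run_pipeline(small_landscape.dataset, small_config)


@pytest.fixture(scope="session")
def big_landscape():
    """The full-scale validation landscape: 2000 sites, 30 species niches
    (a few deliberately too rare to model), 4 variables, 18 reference sites."""
    spec = evdkit.demo_spec(n_sites=2000, n_species=30, n_reference=18, seed=42)
    return evdkit.generate(spec)


@pytest.fixture(scope="session")
def big_result(big_landscape):
    return evdkit.run_pipeline(big_landscape.dataset, RunConfig())


def make_flat_sdm(name="flat", predictors=("s1",), intercept=0.0, linear=None, quadratic=None):
    """An AveragedSDM built directly from coefficients (no fitting)."""
    from evdkit.sdm import AveragedSDM

    predictors = tuple(predictors)
    return AveragedSDM(
        species=name,
        predictors=predictors,
        intercept=intercept,
        linear={v: (linear or {}).get(v, 0.0) for v in predictors},
        quadratic={v: (quadratic or {}).get(v, 0.0) for v in predictors},
        n_models_averaged=1,
        best_aic=0.0,
        auc=0.5,
        n_presences=10,
        n_sites=20,
    )
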