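"""Shared fixtures: small virtual worlds, labelled tables, trained models.

Everything is generated programmatically and seeded; session-scoped
fixtures amortize the more expensive simulation + training steps across
test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import nichecontrast as nc
from nichecontrast.geodata_io import INVASIVE, NATIVE
from nichecontrast.synthetic_world import (TEST_YEAR, TRAIN_YEARS,
                                           make_synthetic_supplement)


def make_toy_table(n_per_class: int = 20, gap: float = 100.0,
                   seed: int = 0, variables=("V1", "V2")) -> nc.FeatureTable:
    """Two well-separated Gaussian clouds (distance >> spread)."""
    rng = np.random.default_rng(seed)
    inv = rng.normal(0.0, 1.0, size=(n_per_class, len(variables)))
    nat = rng.normal(gap, 1.0, size=(n_per_class, len(variables)))
    data = pd.DataFrame(np.vstack([inv, nat]), columns=list(variables))
    data.insert(0, "species", ["inv"] * n_per_class + ["nat"] * n_per_class)
    data.insert(1, "year", 2011)
    data.insert(2, "x", 0.5)
    data.insert(3, "y", 0.5)
    data.insert(4, "label", [INVASIVE] * n_per_class + [NATIVE] * n_per_class)
    return nc.FeatureTable(data, list(variables))


def make_labelled_table(X_inv: np.ndarray, X_nat: np.ndarray,
                        variables) -> nc.FeatureTable:
    """Wrap two covariate matrices into a labelled feature table."""
    data = pd.DataFrame(np.vstack([X_inv, X_nat]), columns=list(variables))
    n_inv, n_nat = len(X_inv), len(X_nat)
    data.insert(0, "species", ["inv"] * n_inv + ["nat"] * n_nat)
    data.insert(1, "year", 2011)
    data.insert(2, "x", 0.5)
    data.insert(3, "y", 0.5)
    data.insert(4, "label", [INVASIVE] * n_inv + [NATIVE] * n_nat)
    return nc.FeatureTable(data, list(variables))


@pytest.fixture(scope="session")
def supplement():
    """The exact-count synthetic stand-in for the per-species tables."""
    return make_synthetic_supplement(seed=7)


@pytest.fixture(scope="session")
def supplement_tables(supplement):
    """(train_table, test_table) with the canonical 8 variables attached."""
    roles = nc.species_role_map()
    records = [r for recs in supplement["records"].values() for r in recs]
    table = nc.attach_features(records, supplement["stacks"],
                               nc.CANONICAL_VARIABLES, roles)
    train_tab = table.subset(table.data["year"].isin(TRAIN_YEARS).to_numpy())
    test_tab = table.subset((table.data["year"] == TEST_YEAR).to_numpy())
    return train_tab, test_tab


@pytest.fixture(scope="session")
def trained_model(supplement_tables):
    """Reference-hyperparameter model trained on the capped training table."""
    train_tab, _ = supplement_tables
    config = nc.TrainingConfig(subsample_seed=1)
    capped = nc.build_training_set(train_tab, config=config)
    return nc.train(capped, config)


@pytest.fixture()
def small_world():
    return nc.WorldConfig(rows=24, cols=24, years=(2011, 2012), seed=11,
                          smoothness=4.0)


@pytest.fixture()
def toy_table():
    return make_toy_table()
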