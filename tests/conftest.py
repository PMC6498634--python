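from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from viosna.categories import CATEGORIES


def make_histories(indicator_sets, wvv=None, age_group="15-24",
                   nationality="foreign", residence="outside") -> pd.DataFrame:
    """Build a minimal history table from per-woman sets of category names."""
    rows = []
    for i, cats in enumerate(indicator_sets):
        unknown = set(cats) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {unknown}")
        row = {c: c in cats for c in CATEGORIES}
        row.update(
            woman_id=f"T{i:04d}",
            age_group=age_group,
            nationality=nationality,
            residence=residence,
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    if wvv is None:
        from viosna.categories import VIOLENCE_CATEGORIES

        df["wvv"] = df[list(VIOLENCE_CATEGORIES)].any(axis=1)
    else:
        df["wvv"] = list(wvv)
    return df


@pytest.fixture
def histories_factory():
    return make_histories


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-parameter synthetic cohort shared across tests."""
    from viosna import synthetic as syn

    cfg = syn.default_config(n_women=20_000)
    return syn.generate_histories(cfg, seed=11), cfg


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
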