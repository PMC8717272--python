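"""Diet-state classification and imputation for percentage diet tables.

Species are assigned one of four diet states from the percentages of
insects/invertebrates, plants, and fruits+seeds in their diet: a
specialist state when a single category reaches 50% while the others
stay below it, and generalist otherwise.  Missing percentage rows are
filled by iterative random-forest regression on the observed percentage
columns only — deliberately without phylogenetic predictors, so that
imputed traits are not forced to covary with the phylogeny they are
later mapped on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

__all__ = [
    "DIET_STATES",
    "PCT_COLUMNS",
    "classify_diet",
    "classify_table",
    "impute_diet",
    "read_diet_csv",
    "write_diet_csv",
]

# canonical state order used by the Mk machinery downstream
DIET_STATES = ("insectivore", "plant_eater", "fruit_seed_eater", "generalist")
PCT_COLUMNS = ("pct_insect", "pct_plant", "pct_fruitseed")
THRESHOLD = 50.0


def classify_diet(pct_insect: float, pct_plant: float,
                  pct_fruitseed: float) -> str:
    """Four-way diet state from raw percentages.

    A specialist state requires its category at >= 50% with both others
    < 50%; everything else (including exact 50/50 ties between two
    categories) is generalist, the residual omnivore category.
    Percentages are not renormalized to sum to 100.
    """
    vals = (pct_insect, pct_plant, pct_fruitseed)
    for v in vals:
        if v is None or not np.isfinite(v):
            raise ValueError("missing diet percentage; impute first")
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"diet percentage {v} outside [0, 100]")
    hits = [v >= THRESHOLD for v in vals]
    if sum(hits) == 1:
        return DIET_STATES[hits.index(True)]
    return "generalist"


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add/overwrite the ``state`` column of a diet table."""
    out = table.copy()
    out["state"] = [
        classify_diet(r.pct_insect, r.pct_plant, r.pct_fruitseed)
        for r in out.itertuples()
    ]
    return out


def impute_diet(table: pd.DataFrame, seed: int = 0,
                max_iter: int = 10) -> pd.DataFrame:
    """Fill missing diet percentages by iterative ensemble regression.

    Each percentage column with missing entries is regressed on the
    others with a random forest, cycling until the imputations stop
    changing (or ``max_iter`` rounds).  Observed cells are never
    altered; imputed values are clipped to [0, 100].  Deterministic for
    a fixed seed.
    """
    for col in PCT_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"diet table missing column {col!r}")
        if table[col].isna().all():
            raise ValueError(f"column {col!r} is entirely missing; "
                             "cannot impute")
    X = table.loc[:, list(PCT_COLUMNS)].to_numpy(dtype=float)
    n_missing_rows = int(np.isnan(X).any(axis=1).sum())
    if n_missing_rows == 0:
        return table.copy()
    if n_missing_rows / len(table) >= 0.5:
        raise ValueError(
            f"{n_missing_rows}/{len(table)} species have missing diet data; "
            "imputation requires < 50% missing")
    imputer = IterativeImputer(
        estimator=RandomForestRegressor(n_estimators=100, random_state=seed),
        max_iter=max_iter, random_state=seed, sample_posterior=False,
        min_value=0.0, max_value=100.0)
    filled = imputer.fit_transform(X)
    out = table.copy()
    observed = ~np.isnan(X)
    filled[observed] = X[observed]
    out.loc[:, list(PCT_COLUMNS)] = np.clip(filled, 0.0, 100.0)
    return out


def read_diet_csv(path: str) -> pd.DataFrame:
    """Read a diet table CSV (species, pct_insect, pct_plant, pct_fruitseed[, state])."""
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError("diet CSV must have a 'species' column")
    return df


def write_diet_csv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False)


def states_as_integers(table: pd.DataFrame) -> dict[str, int]:
    """Map species -> canonical integer state for the Mk machinery."""
    if "state" not in table.columns:
        table = classify_table(table)
    index = {s: i for i, s in enumerate(DIET_STATES)}
    return {r.species: index[r.state] for r in table.itertuples()}
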