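"""Elevational constraint of ecomorphs and its relationship with body mass.

Each ecomorph-island pair gets an *elevational constraint*: the Spearman
rank correlation between the ecomorph's habitat suitability surface and
elevation over the island's valid cells (high positive r = restricted to
high elevations).  These constraints are then rank-correlated against the
fixed ordinal body-mass ranking of the ecomorphs

    twig < grass-bush < trunk < trunk-crown < trunk-ground < crown-giant

with a seeded permutation p-value.  A negative trait correlation means
lighter ecomorphs are the more elevation-restricted ones.

Because Spearman correlation is invariant to monotone rescaling, it does
not matter whether the raw logistic ensemble mean or a min-max-scaled copy
is supplied as the suitability surface.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .envstats import _spearman_r, spearman_perm
from .io_formats import GridRaster

logger = logging.getLogger("eccpipe")

__all__ = [
    "MASS_RANKS",
    "mass_rank",
    "elevational_constraint",
    "constraint_table",
    "trait_correlation",
    "flag_outliers",
]

#: Ordinal body-mass ranking, lightest (1) to heaviest (6).
MASS_RANKS: dict[str, int] = {
    "twig": 1,
    "grass-bush": 2,
    "trunk": 3,
    "trunk-crown": 4,
    "trunk-ground": 5,
    "crown-giant": 6,
}


def mass_rank(ecomorph: str) -> int:
    """The ecomorph's ordinal body-mass rank; unknown names are rejected."""
    try:
        return MASS_RANKS[ecomorph]
    except KeyError:
        raise KeyError(
            f"unknown ecomorph {ecomorph!r}; expected one of {sorted(MASS_RANKS)}"
        ) from None


def elevational_constraint(
    suitability: GridRaster,
    elevation: GridRaster,
    subsample: np.ndarray | None = None,
) -> tuple[float, int]:
    """Spearman r between suitability and elevation over valid cells.

    ``subsample`` optionally restricts the computation to positional
    indices into the valid-cell vector (default: the full point set).
    """
    if not np.array_equal(suitability.mask, elevation.mask):
        raise ValueError("suitability and elevation masks differ")
    s = suitability.masked_values()
    e = elevation.masked_values()
    if subsample is not None:
        s, e = s[subsample], e[subsample]
    if s.size < 5:
        raise ValueError("need at least 5 points")
    if np.ptp(s) == 0:
        raise ValueError("constant suitability: constraint undefined")
    return _spearman_r(s, e), int(s.size)


def constraint_table(
    suitability_maps: dict[str, dict[str, GridRaster]],
    elevations: dict[str, GridRaster],
) -> pd.DataFrame:
    """Constraint r for every (ecomorph, island): columns
    ``ecomorph, island, mass_rank, r, n, excluded``.

    ``suitability_maps`` maps island -> ecomorph -> suitability raster.
    """
    rows = []
    for island, per_eco in suitability_maps.items():
        for eco, suit in per_eco.items():
            if np.ptp(suit.masked_values()) == 0:
                # an all-uniform suitability map (regularization removed every
                # feature) carries no elevational signal: constraint 0
                logger.info("%s/%s: uniform suitability; constraint set to 0", eco, island)
                r, n = 0.0, int(suit.n_valid)
            else:
                r, n = elevational_constraint(suit, elevations[island])
            rows.append(
                {
                    "ecomorph": eco,
                    "island": island,
                    "mass_rank": mass_rank(eco),
                    "r": r,
                    "n": n,
                    "excluded": False,
                }
            )
    return pd.DataFrame(rows)


def trait_correlation(
    table: pd.DataFrame,
    exclude: list[tuple[str, str]] | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Spearman correlation (permutation p) between constraint r and mass rank.

    ``exclude`` lists (ecomorph, island) rows to leave out of the statistic;
    they stay in the returned table with ``excluded = True``.
    """
    table = table.copy()
    exclude = exclude or []
    for eco, island in exclude:
        hit = (table["ecomorph"] == eco) & (table["island"] == island)
        if not hit.any():
            raise ValueError(f"exclusion ({eco!r}, {island!r}) matches no row")
        table.loc[hit, "excluded"] = True
    used = table[~table["excluded"]]
    if len(used) < 5:
        raise ValueError("fewer than 5 non-excluded rows")
    r, p = spearman_perm(
        used["r"].to_numpy(),
        used["mass_rank"].to_numpy(dtype=float),
        n_permutations=max(n_permutations, 1000),
        seed=seed,
    )
    return r, p, table


def flag_outliers(table: pd.DataFrame, method: str = "iqr") -> pd.DataFrame:
    """Flag rows far off the rank trend for review (never auto-exclude).

    ``iqr``: fit a robust Theil-Sen line of constraint r on mass rank
    (so a single aberrant row cannot drag the trend toward itself), compute
    residuals, and flag rows with |residual - median| > 1.5 IQR (with a
    small absolute floor so numerically perfect trends flag nothing).
    ``none`` flags nothing.  Returns the flagged rows (possibly empty).
    """
    if method not in {"none", "iqr"}:
        raise ValueError("method must be 'none' or 'iqr'")
    if len(table) < 5:
        raise ValueError("need at least 5 rows")
    if method == "none":
        return table.iloc[0:0]
    slope, intercept, *_ = stats.theilslopes(
        table["r"].to_numpy(), table["mass_rank"].to_numpy(dtype=float)
    )
    resid = table["r"].to_numpy() - (intercept + slope * table["mass_rank"].to_numpy())
    q1, q3 = np.percentile(resid, [25, 75])
    iqr = q3 - q1
    med = np.median(resid)
    flagged = np.abs(resid - med) > max(1.5 * iqr, 1e-9)
    if flagged.any():
        logger.info("flagged %d potential outlier row(s) for review", int(flagged.sum()))
    return table[flagged]
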