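"""Point extraction, bioclimatic PCA, decorrelated subsampling and the
ECC-environment correlation statistics.

The full point dataset (one row per valid grid cell) yields raster-level
Pearson correlations between ECC and elevation.  Because neighbouring cells
are strongly redundant, p-values are computed on a reduced dataset: the
climate PCA scores are clustered with k-means (k = 100 by default) and 1 or
10 points are drawn at random from each cluster, which decorrelates the
sample while spanning the island's climate space.  The reduced dataset gets
a Spearman rank correlation with a seeded two-sided permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .community import ECCMap, ecc
from .io_formats import EnvStack, GridRaster, RunConfig

logger = logging.getLogger("eccpipe")

__all__ = [
    "BioPCResult",
    "CorrelationResult",
    "ElevationDependence",
    "extract_points",
    "pca_bioclim",
    "kmeans_subsample",
    "raster_correlation",
    "spearman_perm",
    "kruskal_wallis",
    "classify_elevation_dependence",
    "correlation_pipeline",
    "ecc_sensitivity",
]


@dataclass
class BioPCResult:
    """Correlation-matrix PCA of the climate variables.

    ``retained`` counts eigenvalues > 1 (Kaiser criterion); ``scores`` holds
    all components (columns BioPC1, BioPC2, ...), of which the first
    ``retained`` are the BioPCs used downstream.
    """

    loadings: pd.DataFrame  # variables x components
    eigenvalues: np.ndarray  # non-increasing
    retained: int
    scores: pd.DataFrame  # points x components

    @property
    def retained_scores(self) -> pd.DataFrame:
        return self.scores.iloc[:, : self.retained]


@dataclass
class CorrelationResult:
    """Raster-level and reduced-dataset ECC-elevation correlation."""

    pearson_R: float
    slope: float
    intercept: float
    spearman_r: float
    p_value: float
    n: int  # reduced-dataset size


@dataclass
class ElevationDependence:
    """Partition of BioPCs into elevation-dependent and -independent sets."""

    dependent: list[str]
    independent: list[str]
    all_dependent: bool
    correlations: dict[str, float]


def extract_points(stack: EnvStack, ecc_map: ECCMap) -> pd.DataFrame:
    """One row per valid cell: cell id, island, elevation, climate, ECC.

    Column order: ``cell, row, col, island, elevation, <climate...>, ECC``.
    """
    if not np.array_equal(ecc_map.raster.mask, stack.mask):
        raise ValueError("ECC mask differs from stack mask")
    rows, cols = np.nonzero(stack.mask)
    data: dict[str, np.ndarray | str] = {
        "cell": rows * stack.mask.shape[1] + cols,
        "row": rows,
        "col": cols,
        "island": stack.island_id,
        "elevation": stack.elevation.values[rows, cols],
    }
    for name in stack.climate_names:
        data[name] = stack.layers[name].values[rows, cols]
    data["ECC"] = ecc_map.raster.values[rows, cols]
    return pd.DataFrame(data)


def pca_bioclim(points: pd.DataFrame, climate_cols: list[str] | None = None) -> BioPCResult:
    """PCA on the correlation matrix of the climate columns.

    Variables are standardized, so eigenvalues sum to the number of
    variables; components with eigenvalue > 1 are retained.  A constant
    variable has an undefined correlation and is an error.
    """
    if climate_cols is None:
        reserved = {"cell", "row", "col", "island", "elevation", "ECC"}
        climate_cols = [c for c in points.columns if c not in reserved]
    if len(climate_cols) < 2:
        raise ValueError("need at least 2 climate variables")
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    X = points[climate_cols].to_numpy(dtype=float)
    sds = X.std(axis=0, ddof=1)
    for name, sd in zip(climate_cols, sds):
        if sd == 0.0:
            raise ValueError(f"climate variable {name!r} is constant")
    Z = (X - X.mean(axis=0)) / sds
    corr = (Z.T @ Z) / (len(points) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[pivot, j] < 0:
            eigvec[:, j] *= -1
    comp_names = [f"BioPC{j + 1}" for j in range(len(climate_cols))]
    loadings = pd.DataFrame(eigvec, index=climate_cols, columns=comp_names)
    scores = pd.DataFrame(Z @ eigvec, columns=comp_names, index=points.index)
    retained = int((eigval > 1.0).sum())
    return BioPCResult(
        loadings=loadings, eigenvalues=eigval, retained=retained, scores=scores
    )


def kmeans_subsample(
    scores: np.ndarray | pd.DataFrame,
    k: int,
    per_cluster: int,
    seed: int,
) -> np.ndarray:
    """k-means-stratified subsample of point rows.

    Clusters the score matrix into ``k`` groups and draws ``per_cluster``
    rows uniformly without replacement from each (all rows, with a warning,
    if a cluster is smaller).  Returns sorted positional row indices.
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k = {k} exceeds the {n} available points")
    km = KMeans(n_clusters=k, random_state=int(seed) % 2**32, n_init=10)
    labels = km.fit_predict(X)
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for cluster in range(k):
        members = np.flatnonzero(labels == cluster)
        if members.size == 0:
            continue
        if members.size <= per_cluster:
            if members.size < per_cluster:
                logger.warning(
                    "cluster %d has only %d point(s) (< %d); taking all",
                    cluster, members.size, per_cluster,
                )
            chosen.extend(members.tolist())
        else:
            chosen.extend(rng.choice(members, size=per_cluster, replace=False).tolist())
    return np.array(sorted(chosen), dtype=int)


def raster_correlation(
    ecc_map: ECCMap | GridRaster, elevation: GridRaster
) -> tuple[float, float, float]:
    """Pearson R plus OLS slope/intercept of ECC on elevation, all valid cells."""
    raster = ecc_map.raster if isinstance(ecc_map, ECCMap) else ecc_map
    if not np.array_equal(raster.mask, elevation.mask):
        raise ValueError("ECC mask differs from elevation mask")
    y = raster.masked_values()
    x = elevation.masked_values()
    if x.size < 3:
        raise ValueError("need at least 3 valid cells")
    if x.std() == 0:
        raise ValueError("elevation has zero variance")
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.intercept)


def _spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman r: Pearson correlation of average ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx @ ry) / denom)


def spearman_perm(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rank correlation with a seeded two-sided permutation p-value.

    ``p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_permutations)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 5:
        raise ValueError("need at least 5 points")
    if n_permutations < 1000:
        raise ValueError("need at least 1000 permutations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman r undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    zx = rx - rx.mean()
    zy = ry - ry.mean()
    denom = np.sqrt((zx**2).sum() * (zy**2).sum())
    r_obs = float((zx @ zy) / denom)
    rng = np.random.default_rng(seed)
    n = x.size
    hits = 0
    chunk = max(1, min(n_permutations, 50_000_000 // max(n, 1)))
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        perms = rng.permuted(np.broadcast_to(zy, (b, n)), axis=1)
        r_perm = (perms @ zx) / denom
        hits += int((np.abs(r_perm) >= abs(r_obs) - 1e-12).sum())
        done += b
    p = (1.0 + hits) / (1.0 + n_permutations)
    return r_obs, float(p)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (df = groups - 1)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        H += r.sum() ** 2 / g.size
        start += g.size
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    ties = ((counts**3 - counts).sum()) / (N**3 - N)
    if ties < 1.0:
        H /= 1.0 - ties
    p = float(stats.chi2.sf(H, df=len(groups) - 1))
    return float(H), p


def classify_elevation_dependence(
    biopcs: BioPCResult,
    elevation: np.ndarray,
    threshold: float = 0.5,
) -> ElevationDependence:
    """Partition retained BioPCs by |Pearson r| against elevation.

    A BioPC is elevation-dependent iff ``|r| >= threshold``.  When every
    retained BioPC is dependent the ``all_dependent`` flag is set, which
    switches the downstream candidate-model set to the single-BioPC form.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    elev = np.asarray(elevation, dtype=float)
    correlations: dict[str, float] = {}
    dependent, independent = [], []
    for name in biopcs.retained_scores.columns:
        r = float(np.corrcoef(biopcs.scores[name], elev)[0, 1])
        correlations[name] = r
        (dependent if abs(r) >= threshold else independent).append(name)
    return ElevationDependence(
        dependent=dependent,
        independent=independent,
        all_dependent=len(independent) == 0,
        correlations=correlations,
    )


def correlation_pipeline(
    ecc_map: ECCMap,
    stack: EnvStack,
    config: RunConfig,
    seed: int,
    points: pd.DataFrame | None = None,
    biopcs: BioPCResult | None = None,
) -> CorrelationResult:
    """Raster-level Pearson plus reduced-dataset Spearman for one island."""
    R, slope, intercept = raster_correlation(ecc_map, stack.elevation)
    if points is None:
        points = extract_points(stack, ecc_map)
    if biopcs is None:
        biopcs = pca_bioclim(points)
    idx = kmeans_subsample(
        biopcs.retained_scores.to_numpy(), config.kmeans_k, config.points_per_cluster, seed
    )
    sub = points.iloc[idx]
    r, p = spearman_perm(
        sub["elevation"].to_numpy(),
        sub["ECC"].to_numpy(),
        n_permutations=max(config.n_permutations, 1000),
        seed=seed,
    )
    return CorrelationResult(
        pearson_R=R, slope=slope, intercept=intercept,
        spearman_r=r, p_value=p, n=len(sub),
    )


def ecc_sensitivity(
    maps: dict[str, GridRaster],
    drop: list[str],
    stack: EnvStack,
    config: RunConfig,
    seed: int,
    weights: dict[str, float] | None = None,
) -> tuple[CorrelationResult, CorrelationResult]:
    """Re-run the correlation pipeline with some ecomorphs removed.

    Returns ``(full, reduced)`` correlation results so the sensitivity of
    the ECC-elevation relationship to community composition can be judged.
    Dropping an ecomorph that is not mapped is an error, as is dropping all.
    """
    missing = [d for d in drop if d not in maps]
    if missing:
        raise ValueError(f"cannot drop unmapped ecomorph(s): {missing}")
    kept = {n: m for n, m in maps.items() if n not in set(drop)}
    if not kept:
        raise ValueError("cannot drop every ecomorph")
    full = correlation_pipeline(ecc(maps, weights), stack, config, seed)
    if not drop:
        return full, full
    kept_weights = None if weights is None else {n: weights[n] for n in kept}
    reduced = correlation_pipeline(ecc(kept, kept_weights), stack, config, seed)
    return full, reduced
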