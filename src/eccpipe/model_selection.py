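"""AICc-based multimodel inference for ECC-environment regressions.

Per island, a candidate set of ordinary least-squares models explains ECC
from elevation and the retained bioclimatic principal components (BioPCs):

1. global — elevation + all BioPCs
2. elevation-only
3. all-BioPCs (no elevation)
4. elevation-dependent BioPCs
5. elevation-independent BioPCs

When every BioPC is elevation-dependent (so models 4 and 5 collapse), the
set becomes models 1-3 plus one single-BioPC model per component.

Models are ranked by AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1) with k the
parameter count including intercept and residual variance.  A top Akaike
weight >= 0.9 marks a single most parsimonious model; if the gap between
the two best models is ΔAICc < 3, full-set (shrinkage) model averaging is
applied: a coefficient absent from a model contributes 0, and unconditional
standard errors combine within-model variance with between-model spread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("eccpipe")

__all__ = [
    "ModelSpec",
    "CandidateModel",
    "SelectionTable",
    "build_candidates",
    "fit_linear",
    "aicc_rank",
    "model_average",
    "island_report",
    "select_for_island",
]

SINGLE_BEST_WEIGHT = 0.9
AVERAGING_DELTA = 3.0
VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    name: str
    predictors: tuple[str, ...]


@dataclass
class CandidateModel:
    """One fitted OLS candidate with its information-theoretic scores."""

    name: str
    predictors: tuple[str, ...]
    coefficients: pd.Series  # includes "Intercept"
    std_errors: pd.Series
    residual_variance: float
    log_likelihood: float
    k: int  # predictors + intercept + variance
    aicc: float = float("nan")
    delta: float = float("nan")
    weight: float = float("nan")


@dataclass
class SelectionTable:
    """AICc-ranked candidates for one response."""

    models: list[CandidateModel]  # sorted by AICc ascending
    n: int
    single_best: str | None
    averaging_applied: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [m.name for m in self.models],
                "predictors": ["+".join(m.predictors) or "1" for m in self.models],
                "k": [m.k for m in self.models],
                "logLik": [m.log_likelihood for m in self.models],
                "AICc": [m.aicc for m in self.models],
                "delta": [m.delta for m in self.models],
                "weight": [m.weight for m in self.models],
            }
        )


def build_candidates(
    biopcs: list[str],
    dependent: list[str] | None = None,
    independent: list[str] | None = None,
    all_dependent: bool = False,
) -> list[ModelSpec]:
    """Construct the per-island candidate model set.

    Standard mode requires the dependent/independent partition; the
    all-dependent mode replaces the partition models with one model per
    BioPC.  Empty partition sets drop the corresponding model with a
    warning; duplicate specs (e.g. with a single BioPC) are removed.
    """
    if not biopcs:
        raise ValueError("need at least one BioPC")
    specs = [
        ModelSpec("global", ("elevation", *biopcs)),
        ModelSpec("elevation-only", ("elevation",)),
        ModelSpec("all-biopcs", tuple(biopcs)),
    ]
    if all_dependent:
        specs += [ModelSpec(f"single-{pc}", (pc,)) for pc in biopcs]
    else:
        if dependent is None or independent is None:
            raise ValueError("standard mode needs the dependence partition")
        if dependent:
            specs.append(ModelSpec("elev-dependent", tuple(dependent)))
        else:
            logger.warning("empty elevation-dependent set; model omitted")
        if independent:
            specs.append(ModelSpec("elev-independent", tuple(independent)))
        else:
            logger.warning("empty elevation-independent set; model omitted")
    seen: dict[tuple[str, ...], str] = {}
    unique: list[ModelSpec] = []
    for spec in specs:
        key = tuple(sorted(spec.predictors))
        if key in seen:
            logger.warning("model %r duplicates %r; removed", spec.name, seen[key])
            continue
        seen[key] = spec.name
        unique.append(spec)
    return unique


def fit_linear(y: np.ndarray, X: pd.DataFrame, name: str = "model") -> CandidateModel:
    """OLS fit with Gaussian ML log-likelihood.

    ``X`` holds the predictor columns (no intercept column; one is added).
    A rank-deficient design raises with the offending columns named.
    The ML residual variance is floored at 1e-12 so an exact fit keeps a
    finite log-likelihood.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    p = design.shape[1]
    if n <= p + 1:
        raise ValueError(f"model {name!r}: n = {n} too small for {p} coefficients")
    if np.linalg.matrix_rank(design) < p:
        collinear = _collinear_columns(X)
        raise ValueError(f"model {name!r}: rank-deficient design; suspect columns {collinear}")
    fit = sm.OLS(y, design).fit()
    rss = float(fit.ssr)
    sigma2 = max(rss / n, VARIANCE_FLOOR)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    names = ["Intercept", *X.columns]
    return CandidateModel(
        name=name,
        predictors=tuple(X.columns),
        coefficients=pd.Series(fit.params, index=names),
        std_errors=pd.Series(fit.bse, index=names),
        residual_variance=sigma2,
        log_likelihood=float(loglik),
        k=len(X.columns) + 2,
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    cols = list(X.columns)
    bad = []
    M = X.to_numpy(dtype=float)
    base_rank = np.linalg.matrix_rank(M)
    for i, c in enumerate(cols):
        reduced = np.delete(M, i, axis=1)
        if np.linalg.matrix_rank(reduced) == base_rank:
            bad.append(c)
    return bad or cols


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n = {n}, k = {k}")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_rank(models: list[CandidateModel], n: int) -> SelectionTable:
    """Rank candidates by AICc; compute deltas and Akaike weights.

    Models with ``n <= k + 1`` are rejected (logged).  The single-best flag
    is set iff the top weight reaches 0.9; averaging applies iff the ΔAICc
    between the two best models is < 3.
    """
    usable = []
    for m in models:
        if n <= m.k + 1:
            logger.warning("model %r rejected: n = %d <= k + 1 = %d", m.name, n, m.k + 1)
            continue
        m.aicc = aicc(m.log_likelihood, m.k, n)
        usable.append(m)
    if not usable:
        raise ValueError("no candidate model satisfies n > k + 1")
    usable.sort(key=lambda m: m.aicc)
    best = usable[0].aicc
    deltas = np.array([m.aicc - best for m in usable])
    rel = np.exp(-deltas / 2.0)
    weights = rel / rel.sum()
    for m, d, w in zip(usable, deltas, weights):
        m.delta = float(d)
        m.weight = float(w)
    single_best = usable[0].name if usable[0].weight >= SINGLE_BEST_WEIGHT else None
    averaging = len(usable) > 1 and (usable[1].aicc - usable[0].aicc) < AVERAGING_DELTA
    return SelectionTable(
        models=usable, n=n, single_best=single_best, averaging_applied=averaging
    )


def model_average(
    table: SelectionTable,
    variables: list[str] | None = None,
    force: bool = False,
) -> pd.DataFrame:
    """Full-set (shrinkage) model averaging over the whole candidate set.

    estimate_v = sum_i w_i beta_iv with beta = 0 where v is absent;
    unconditional SE_v = sum_i w_i sqrt(var_i(beta_v) + (beta_iv - est_v)^2);
    CI = estimate ± 1.96 SE; relative importance = sum of weights of models
    containing v.  Refuses to run when a single best model exists (weight
    >= 0.9) unless ``force``.  ``variables`` may list extra variables to
    report (they get estimate 0 and importance 0 if no model contains them).
    """
    if table.single_best is not None and not force:
        raise ValueError(
            f"single most parsimonious model {table.single_best!r} (weight >= 0.9); "
            f"use its coefficients directly instead of averaging"
        )
    requested = variables
    variables = ["Intercept"]
    for m in table.models:
        for v in m.predictors:
            if v not in variables:
                variables.append(v)
    for v in requested or []:
        if v not in variables:
            variables.append(v)
    rows = []
    for v in variables:
        est = sum(m.weight * m.coefficients.get(v, 0.0) for m in table.models)
        se = sum(
            m.weight
            * np.sqrt(m.std_errors.get(v, 0.0) ** 2 + (m.coefficients.get(v, 0.0) - est) ** 2)
            for m in table.models
        )
        importance = sum(
            m.weight for m in table.models if v in m.predictors or v == "Intercept"
        )
        rows.append(
            {
                "variable": v,
                "estimate": est,
                "se": se,
                "ci_low": est - 1.96 * se,
                "ci_high": est + 1.96 * se,
                "importance": importance if v != "Intercept" else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def select_for_island(
    points: pd.DataFrame,
    biopc_scores: pd.DataFrame,
    dependent: list[str],
    independent: list[str],
    all_dependent: bool,
) -> SelectionTable:
    """Fit and rank the full candidate set for one island's point table."""
    y = points["ECC"].to_numpy(dtype=float)
    predictors = pd.concat(
        [points[["elevation"]].reset_index(drop=True), biopc_scores.reset_index(drop=True)],
        axis=1,
    )
    specs = build_candidates(
        list(biopc_scores.columns),
        dependent=dependent,
        independent=independent,
        all_dependent=all_dependent,
    )
    models = [fit_linear(y, predictors[list(s.predictors)], name=s.name) for s in specs]
    return aicc_rank(models, n=len(points))


def island_report(tables: dict[str, SelectionTable]) -> pd.DataFrame:
    """Summary across islands: per model, "ΔAICc / weight"; absent models N/A."""
    if not tables:
        raise ValueError("need at least one island")
    model_names: list[str] = []
    for t in tables.values():
        for m in t.models:
            if m.name not in model_names:
                model_names.append(m.name)
    out = pd.DataFrame(index=model_names, columns=list(tables), dtype=object)
    out[:] = "N/A"
    for island, t in tables.items():
        for m in t.models:
            out.loc[m.name, island] = f"{m.delta:.4g} / {m.weight:.4g}"
    out.index.name = "model"
    return out
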