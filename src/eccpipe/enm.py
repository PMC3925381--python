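"""Presence-background (maximum-entropy) niche models.

The model is the Gibbs distribution over landscape cells

    q_lambda(x) = exp(lambda . f(x)) / Z,   Z = sum_background exp(lambda . f(x)),

whose feature expectations are pulled toward the presence sample by
maximizing the L1-penalized presence log-likelihood

    (1/m) sum_presence lambda . f(x)  -  log Z(lambda)  -  sum_j beta_j |lambda_j|.

Features are linear and quadratic terms of each environmental layer,
standardized on the background sample.  The penalty scale follows
``beta_j = beta0 * s_j / sqrt(m)`` with ``s_j`` the presence-sample
standard deviation of feature j and ``m`` the presence count.

The objective is convex; it is minimized exactly (the L1 term included)
by splitting ``lambda = u - v`` with ``u, v >= 0``, which makes the
problem smooth with box constraints, and running L-BFGS-B.

The logistic output calibrates "typical" sites to 0.5: with H the entropy
of q over the background, ``p(x) = 1 / (1 + exp(-(H + log q(x))))``, so a
cell with ``q = exp(-H)`` scores exactly 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import rankdata

from .io_formats import EnvStack, GridRaster, OccurrenceSet, RunConfig

logger = logging.getLogger("eccpipe")

__all__ = [
    "FeatureSpec",
    "MaxentModel",
    "SuitabilityEnsemble",
    "ConvergenceError",
    "draw_background",
    "fit_maxent",
    "logistic_map",
    "logistic_from_log",
    "auc",
    "auc_scores",
    "fit_ensemble",
    "penalized_objective",
]


class ConvergenceError(RuntimeError):
    """Optimization failed to meet the stationarity criteria."""


@dataclass
class FeatureSpec:
    """Linear/quadratic feature construction with background standardization.

    Layers that are constant over the background are dropped with a warning
    (their standardization would divide by zero).
    """

    layer_names: list[str]
    means: np.ndarray  # per layer, background mean
    sds: np.ndarray  # per layer, background sd (> 0)
    include_linear: bool = True
    include_quadratic: bool = True

    @classmethod
    def from_background(
        cls,
        stack: EnvStack,
        background_cells: list[tuple[int, int]],
        layers: list[str] | None = None,
        include_linear: bool = True,
        include_quadratic: bool = True,
    ) -> "FeatureSpec":
        """Standardization constants from the background; ``layers`` defaults
        to every layer in the stack."""
        rows = np.array([c[0] for c in background_cells])
        cols = np.array([c[1] for c in background_cells])
        names, means, sds = [], [], []
        use = list(stack.layers) if layers is None else layers
        for name in use:
            layer = stack.layers[name]
            vals = layer.values[rows, cols]
            sd = float(vals.std())
            if sd == 0.0:
                logger.warning("layer %r constant over background; dropped", name)
                continue
            names.append(name)
            means.append(float(vals.mean()))
            sds.append(sd)
        if not names:
            raise ValueError("every layer is constant over the background")
        return cls(
            layer_names=names,
            means=np.array(means),
            sds=np.array(sds),
            include_linear=include_linear,
            include_quadratic=include_quadratic,
        )

    @property
    def feature_names(self) -> list[str]:
        out = []
        if self.include_linear:
            out += [f"{n}:lin" for n in self.layer_names]
        if self.include_quadratic:
            out += [f"{n}:quad" for n in self.layer_names]
        return out

    def matrix(self, stack: EnvStack, cells: list[tuple[int, int]] | np.ndarray) -> np.ndarray:
        """Feature matrix (n_cells x n_features) at the given cells."""
        missing = [n for n in self.layer_names if n not in stack.layers]
        if missing:
            raise KeyError(f"stack {stack.island_id!r} lacks layer(s) {missing}")
        cells = np.asarray(cells)
        rows, cols = cells[:, 0], cells[:, 1]
        z = np.column_stack(
            [
                (stack.layers[n].values[rows, cols] - m) / s
                for n, m, s in zip(self.layer_names, self.means, self.sds)
            ]
        )
        blocks = []
        if self.include_linear:
            blocks.append(z)
        if self.include_quadratic:
            blocks.append(z**2)
        F = np.hstack(blocks)
        if not np.isfinite(F).all():
            raise ValueError("non-finite feature values")
        return F


@dataclass
class MaxentModel:
    """A fitted Gibbs model: weights, normalizer, entropy and diagnostics."""

    lam: np.ndarray  # one weight per feature
    Z: float  # normalizer over the background sample
    H: float  # entropy of q over the background, nats
    feature_spec: FeatureSpec
    penalties: np.ndarray  # beta_j actually applied
    n_presence: int
    n_background: int
    train_auc: float = float("nan")
    test_auc: float = float("nan")
    # kept for stationarity diagnostics / oracle checks
    F_presence: np.ndarray | None = field(default=None, repr=False)
    F_background: np.ndarray | None = field(default=None, repr=False)

    def log_raw(self, stack: EnvStack, cells) -> np.ndarray:
        """log q at arbitrary cells (normalized by the fit's background Z)."""
        F = self.feature_spec.matrix(stack, cells)
        return F @ self.lam - np.log(self.Z)

    def raw(self, stack: EnvStack, cells) -> np.ndarray:
        return np.exp(self.log_raw(stack, cells))

    def logistic(self, stack: EnvStack, cells) -> np.ndarray:
        return expit(self.H + self.log_raw(stack, cells))


@dataclass
class SuitabilityEnsemble:
    """Replicate logistic suitability maps and their cellwise mean."""

    replicates: list[GridRaster]
    mean_map: GridRaster
    test_aucs: list[float]
    models: list[MaxentModel] = field(default_factory=list, repr=False)

    @property
    def mean_test_auc(self) -> float:
        return float(np.mean(self.test_aucs))


def draw_background(stack: EnvStack, n: int, seed: int) -> list[tuple[int, int]]:
    """Draw background cells uniformly without replacement from the mask.

    If ``n`` reaches or exceeds the valid-cell count, every valid cell is
    returned (with a warning).
    """
    cells = stack.valid_cells()
    if not cells:
        raise ValueError(f"island {stack.island_id!r} has an empty mask")
    if n >= len(cells):
        if n > len(cells):
            logger.warning(
                "background request %d exceeds %d valid cells; using all", n, len(cells)
            )
        return cells
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cells), size=n, replace=False)
    return [cells[i] for i in sorted(idx)]


def penalized_objective(
    lam: np.ndarray, F_presence: np.ndarray, F_background: np.ndarray, betas: np.ndarray
) -> float:
    """Negative penalized presence log-likelihood (the quantity minimized)."""
    lam = np.asarray(lam, dtype=float)
    return float(
        -F_presence.mean(axis=0) @ lam
        + logsumexp(F_background @ lam)
        + betas @ np.abs(lam)
    )


def _newton_polish(
    lam: np.ndarray,
    mean_p: np.ndarray,
    F_b: np.ndarray,
    betas: np.ndarray,
    n_steps: int = 30,
):
    """Damped Newton refinement of the active coordinates.

    L-BFGS-B stops on relative objective change; a few Newton steps on the
    smooth part (holding the L1 active set fixed, zeroing coordinates that
    cross zero) push the subgradient residual to the stated tolerance.
    """
    lam = lam.copy()
    for _ in range(n_steps):
        scores = F_b @ lam
        lse = logsumexp(scores)
        q = np.exp(scores - lse)
        grad = -mean_p + F_b.T @ q
        active = (np.abs(lam) > 1e-10) | (np.abs(grad) > betas + 1e-8)
        if not active.any():
            break
        sign = np.where(lam != 0.0, np.sign(lam), -np.sign(grad))
        g_pen = grad[active] + sign[active] * betas[active]
        if np.max(np.abs(g_pen)) < 1e-8:
            break
        Fa = F_b[:, active]
        Fq = Fa * q[:, None]
        hess = Fa.T @ Fq - np.outer(Fq.sum(axis=0), Fq.sum(axis=0))
        hess[np.diag_indices_from(hess)] += 1e-10
        try:
            step = np.linalg.solve(hess, g_pen)
        except np.linalg.LinAlgError:
            break
        # backtracking on the penalized objective
        obj0 = -mean_p @ lam + lse + betas @ np.abs(lam)
        t = 1.0
        for _ in range(40):
            trial = lam.copy()
            trial[active] = lam[active] - t * step
            crossed = np.sign(trial) * np.sign(lam) < 0
            trial[crossed] = 0.0
            obj = -mean_p @ trial + logsumexp(F_b @ trial) + betas @ np.abs(trial)
            if obj <= obj0 - 1e-16:
                lam = trial
                break
            t *= 0.5
        else:
            break
    scores = F_b @ lam
    lse = logsumexp(scores)
    q = np.exp(scores - lse)
    grad = -mean_p + F_b.T @ q
    return lam, scores, lse, q, grad


def fit_maxent(
    presence_cells: list[tuple[int, int]],
    background_cells: list[tuple[int, int]],
    stack: EnvStack,
    feature_spec: FeatureSpec | None = None,
    beta: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> MaxentModel:
    """Fit the L1-penalized Gibbs model.

    Raises :class:`ConvergenceError` if the returned point violates the
    subgradient stationarity conditions (|grad| <= beta_j + 1e-6 for
    inactive weights, |grad + sign * beta_j| < 1e-6 for active ones).
    """
    if len(presence_cells) < 5:
        raise ValueError("need at least 5 presence cells")
    if feature_spec is None:
        feature_spec = FeatureSpec.from_background(stack, background_cells)
    F_p = feature_spec.matrix(stack, presence_cells)
    F_b = feature_spec.matrix(stack, background_cells)
    m, J = F_p.shape
    s_j = F_p.std(axis=0)
    betas = beta * s_j / np.sqrt(m)
    mean_p = F_p.mean(axis=0)

    def split_obj(theta: np.ndarray) -> tuple[float, np.ndarray]:
        u, v = theta[:J], theta[J:]
        lam = u - v
        scores = F_b @ lam
        lse = logsumexp(scores)
        q = np.exp(scores - lse)
        grad_smooth = -mean_p + F_b.T @ q
        obj = -mean_p @ lam + lse + betas @ (u + v)
        return obj, np.concatenate([grad_smooth + betas, -grad_smooth + betas])

    theta0 = np.zeros(2 * J)
    res = minimize(
        split_obj,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * J),
        options={"maxiter": max_iter, "maxfun": 10 * max_iter, "ftol": 1e-15, "gtol": 1e-10},
    )
    lam = res.x[:J] - res.x[J:]
    lam, scores, lse, q, grad = _newton_polish(lam, mean_p, F_b, betas)
    active = np.abs(lam) > 1e-8
    ok_active = np.all(np.abs(grad[active] + np.sign(lam[active]) * betas[active]) < 1e-5)
    ok_inactive = np.all(np.abs(grad[~active]) <= betas[~active] + 1e-5)
    if not (ok_active and ok_inactive):
        raise ConvergenceError(
            f"stationarity violated: status={res.status} msg={res.message!r} "
            f"max|grad_active|={np.max(np.abs(grad[active] + np.sign(lam[active]) * betas[active]), initial=0.0):.2e} "
            f"max(|grad_inactive|-beta)={np.max(np.abs(grad[~active]) - betas[~active], initial=0.0):.2e}"
        )
    Z = float(np.exp(lse))
    H = float(-(q * (scores - lse)).sum())
    model = MaxentModel(
        lam=lam,
        Z=Z,
        H=H,
        feature_spec=feature_spec,
        penalties=betas,
        n_presence=m,
        n_background=len(background_cells),
        F_presence=F_p,
        F_background=F_b,
    )
    model.train_auc = auc(model, stack, presence_cells, background_cells)
    return model


def logistic_from_log(log_q: np.ndarray | float, H: float) -> np.ndarray | float:
    """Logistic suitability from log raw scores: expit(H + log q)."""
    return expit(H + np.asarray(log_q, dtype=float)) if np.ndim(log_q) else expit(H + log_q)


def logistic_map(model: MaxentModel, stack: EnvStack) -> GridRaster:
    """Logistic suitability surface over a stack's valid cells.

    The stack may be a different island than the one the model was fitted
    on (projection); its layers must cover the model's features.
    """
    cells = np.argwhere(stack.mask)
    p = expit(model.H + model.log_raw(stack, cells))
    values = np.zeros(stack.mask.shape)
    values[stack.mask] = p
    return stack.elevation.with_values(values, name="logistic_suitability")


def auc_scores(pos: np.ndarray, neg: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC with ties counted 0.5."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0:
        raise ValueError("need at least one positive score")
    if neg.size == 0:
        raise ValueError("empty background scores")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def auc(
    model: MaxentModel,
    stack: EnvStack,
    presence_cells: list[tuple[int, int]],
    background_cells: list[tuple[int, int]],
) -> float:
    """AUC of model scores: test presences vs background cells."""
    pos = model.log_raw(stack, presence_cells)
    neg = model.log_raw(stack, background_cells)
    return auc_scores(pos, neg)


def fit_ensemble(
    occ: OccurrenceSet,
    stack: EnvStack,
    config: RunConfig,
    projections: dict[str, EnvStack] | None = None,
    combine: str = "mean",
    feature_layers: list[str] | None = None,
) -> SuitabilityEnsemble | dict[str, SuitabilityEnsemble]:
    """Fit a replicate ensemble with held-out AUC.

    Each replicate draws a fresh seeded 75/25 (``1 - test_fraction`` /
    ``test_fraction``) train/test split and a fresh background sample, fits
    the penalized Gibbs model, records the test AUC, and evaluates the
    logistic map on the requested projection stacks (default: the fitting
    island itself).  Replicate maps are combined cellwise by ``combine``
    ("mean" or "median").

    ``feature_layers`` defaults to the stack's climate layers: elevation is
    deliberately left out of the niche models so that the downstream
    ECC-elevation statistics relate completeness to a variable the models
    never saw directly (elevation acts only through the climate it shapes).

    Returns a single :class:`SuitabilityEnsemble` when ``projections`` is
    None, else one per projection island id.
    """
    if len(occ) < 8:
        raise ValueError(
            f"{occ.ecomorph}/{occ.island_id}: {len(occ)} occurrences; need >= 8 so a "
            f"75/25 split keeps at least 2 test points"
        )
    if combine not in {"mean", "median"}:
        raise ValueError("combine must be 'mean' or 'median'")
    targets = projections if projections is not None else {stack.island_id: stack}
    root = np.random.SeedSequence(config.seed)
    rep_seeds = root.spawn(config.n_replicates)
    cells = np.array(occ.cells)
    n_test = max(1, int(round(config.test_fraction * len(cells))))
    maps: dict[str, list[GridRaster]] = {k: [] for k in targets}
    test_aucs: list[float] = []
    models: list[MaxentModel] = []
    for r in range(config.n_replicates):
        child = rep_seeds[r]
        rng = np.random.default_rng(child)
        perm = rng.permutation(len(cells))
        test = [tuple(c) for c in cells[perm[:n_test]]]
        train = [tuple(c) for c in cells[perm[n_test:]]]
        bg_seed = int(child.generate_state(2)[1] % 2**31)
        background = draw_background(stack, config.n_background, seed=bg_seed)
        spec = FeatureSpec.from_background(
            stack,
            background,
            layers=stack.climate_names if feature_layers is None else feature_layers,
        )
        model = fit_maxent(
            train, background, stack, feature_spec=spec, beta=config.regularization
        )
        model.test_auc = auc(model, stack, test, background)
        test_aucs.append(model.test_auc)
        models.append(model)
        for island_id, target in targets.items():
            maps[island_id].append(logistic_map(model, target))
    out: dict[str, SuitabilityEnsemble] = {}
    reducer = np.mean if combine == "mean" else np.median
    for island_id, target in targets.items():
        stackmaps = np.stack([m.values for m in maps[island_id]])
        mean_values = reducer(stackmaps, axis=0)
        mean_map = target.elevation.with_values(
            np.where(target.mask, mean_values, 0.0), name=f"suitability:{occ.ecomorph}"
        )
        out[island_id] = SuitabilityEnsemble(
            replicates=maps[island_id],
            mean_map=mean_map,
            test_aucs=test_aucs,
            models=models,
        )
    if projections is None:
        return out[stack.island_id]
    return out
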