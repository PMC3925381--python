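"""Ecomorph community completeness (ECC) surfaces and niche overlap.

ECC is the cellwise weighted sum of per-ecomorph suitability maps, each
min-max rescaled to [0, 1] beforehand so the scaling is equal between
ecomorphs; with unit weights and six ecomorphs the surface ranges over
[0, 6].  Niche overlap between two suitability/ECC surfaces is Schoener's
D = 1 - 0.5 * sum |p_a - p_b| after normalizing each surface to sum to 1
over the shared valid cells.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GridRaster

logger = logging.getLogger("eccpipe")

__all__ = [
    "ECCMap",
    "minmax_scale",
    "ecc",
    "schoener_d",
    "overlap_matrix",
    "overlap_report",
]

ABSENT = "Ecomorph absent"


@dataclass
class ECCMap:
    """Per-cell sum of rescaled ecomorph suitabilities."""

    raster: GridRaster
    ecomorphs: list[str]
    weights: np.ndarray

    @property
    def max_possible(self) -> float:
        return float(self.weights.sum())


def minmax_scale(r: GridRaster) -> GridRaster:
    """Rescale a raster's valid cells linearly onto [0, 1].

    A constant raster has no defined scaling and raises ``ValueError``.
    """
    vals = r.masked_values()
    if vals.size == 0:
        raise ValueError(f"raster {r.name!r} has no valid cells")
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise ValueError(
            f"raster {r.name!r} is constant ({lo}); min-max scaling is undefined"
        )
    scaled = np.zeros_like(r.values)
    scaled[r.mask] = (vals - lo) / (hi - lo)
    return r.with_values(scaled)


def ecc(
    maps: dict[str, GridRaster],
    weights: dict[str, float] | None = None,
    scale: bool = True,
) -> ECCMap:
    """Weighted sum of per-ecomorph suitability maps.

    ``scale=True`` (default) min-max rescales each map first.  All maps
    must share the mask; weights default to 1 for every ecomorph.
    """
    if not maps:
        raise ValueError("no suitability maps given")
    names = list(maps)
    ref = maps[names[0]]
    for n in names[1:]:
        if not np.array_equal(maps[n].mask, ref.mask):
            raise ValueError(f"map {n!r} mask differs from {names[0]!r}")
    w = np.array([1.0 if weights is None else float(weights[n]) for n in names])
    if (w < 0).any():
        raise ValueError("ECC weights must be >= 0")
    total = np.zeros_like(ref.values)
    for n, wi in zip(names, w):
        layer = minmax_scale(maps[n]) if scale else maps[n]
        total = total + wi * np.where(ref.mask, layer.values, 0.0)
    raster = ref.with_values(np.where(ref.mask, total, 0.0), name="ECC")
    return ECCMap(raster=raster, ecomorphs=names, weights=w)


def _as_valid_vector(a: GridRaster | np.ndarray, b: GridRaster | np.ndarray):
    """Align two surfaces on their shared valid cells; return value vectors."""
    if isinstance(a, GridRaster) and isinstance(b, GridRaster):
        if a.values.shape != b.values.shape:
            raise ValueError("rasters have different shapes")
        inter = a.mask & b.mask
        excluded = int((a.mask ^ b.mask).sum())
        if excluded:
            logger.info("schoener_d: %d cell(s) valid in only one raster excluded", excluded)
        return a.values[inter], b.values[inter]
    va, vb = np.asarray(a, dtype=float).ravel(), np.asarray(b, dtype=float).ravel()
    if va.shape != vb.shape:
        raise ValueError("value vectors have different lengths")
    return va, vb


def schoener_d(a: GridRaster | np.ndarray, b: GridRaster | np.ndarray) -> float:
    """Schoener's D niche overlap between two non-negative surfaces.

    Each surface is normalized to sum to 1 over the shared valid cells
    (so D is invariant to positive rescaling of either input);
    D = 1 - 0.5 * sum |p_a - p_b|, in [0, 1].
    """
    va, vb = _as_valid_vector(a, b)
    if va.size == 0:
        raise ValueError("no shared valid cells")
    if (va < 0).any() or (vb < 0).any():
        raise ValueError("Schoener's D requires non-negative surfaces")
    ta, tb = va.sum(), vb.sum()
    if ta <= 0 or tb <= 0:
        raise ValueError("all-zero surface: normalization undefined")
    d = 1.0 - 0.5 * np.abs(va / ta - vb / tb).sum()
    return float(min(max(d, 0.0), 1.0))


def overlap_matrix(surfaces: dict[str, GridRaster | np.ndarray]) -> pd.DataFrame:
    """Symmetric Schoener's D matrix between named surfaces (diagonal 1)."""
    if len(surfaces) < 2:
        raise ValueError("need at least 2 surfaces for an overlap matrix")
    names = list(surfaces)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, j in itertools.combinations(range(len(names)), 2):
        d = schoener_d(surfaces[names[i]], surfaces[names[j]])
        out.iloc[i, j] = out.iloc[j, i] = d
    return out


def overlap_report(
    ecc_surfaces: dict[str, np.ndarray | GridRaster],
    ecomorph_surfaces: dict[str, dict[str, np.ndarray | GridRaster]],
) -> pd.DataFrame:
    """Pairwise-overlap table: one row per island pair, ECC plus per-ecomorph D.

    ``ecc_surfaces`` maps source island -> cross-fitted ECC surface on the
    common extent; ``ecomorph_surfaces`` maps ecomorph -> source island ->
    surface.  An ecomorph missing from either island of a pair is flagged
    as ``"Ecomorph absent"``, as in presence/absence-aware overlap tables.
    """
    islands = list(ecc_surfaces)
    if len(islands) < 2:
        raise ValueError("need at least 2 islands")
    rows = []
    for a, b in itertools.combinations(islands, 2):
        row: dict[str, object] = {"pair": f"{a}/{b}"}
        row["ECC"] = schoener_d(ecc_surfaces[a], ecc_surfaces[b])
        for eco, per_island in ecomorph_surfaces.items():
            if a in per_island and b in per_island:
                row[eco] = schoener_d(per_island[a], per_island[b])
            else:
                row[eco] = ABSENT
        rows.append(row)
    return pd.DataFrame(rows).set_index("pair")
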