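"""End-to-end orchestration on a synthetic archipelago.

Stages: simulate the landscape, fit a replicate niche-model ensemble per
ecomorph per island (projected to every island for cross-fitting), build
per-island and cross-fitted ECC surfaces, compute the niche-overlap table,
run ECC-elevation correlations on full and reduced point sets, compete the
AICc candidate models, and relate elevational constraint to body-mass rank.
Every stage is seeded from the run configuration, so the whole run is
reproducible bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, enm, envstats, model_selection, synthetic_landscape, traits
from .io_formats import EnvStack, GridRaster, OccurrenceSet, RunConfig, write_json, write_raster, write_occurrences

logger = logging.getLogger("eccpipe")

__all__ = ["run_pipeline", "cross_fitted_surfaces", "PipelineResult"]


def _derived_seed(base: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=base, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % 2**31)


def cross_fitted_surfaces(
    ensembles: dict[tuple[str, str], dict[str, enm.SuitabilityEnsemble]],
    islands: list[str],
    weights: dict[str, float] | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, dict[str, np.ndarray]]]:
    """Cross-fitted ECC and per-ecomorph surfaces on the common extent.

    ``ensembles[(island, ecomorph)]`` maps target island -> ensemble.  For
    each source island, the per-ecomorph mean maps projected onto *every*
    island are concatenated (fixed island order) into one vector over the
    common extent, min-max scaled over that extent, and summed into the
    source island's cross-fitted ECC.
    """
    ecc_vectors: dict[str, np.ndarray] = {}
    eco_vectors: dict[str, dict[str, np.ndarray]] = {}
    for (source, eco), per_target in sorted(ensembles.items()):
        vec = np.concatenate(
            [per_target[t].mean_map.masked_values() for t in islands]
        )
        lo, hi = vec.min(), vec.max()
        if hi == lo:
            raise ValueError(f"constant cross-fitted surface for {eco}/{source}")
        scaled = (vec - lo) / (hi - lo)
        eco_vectors.setdefault(eco, {})[source] = scaled
        w = 1.0 if weights is None else float(weights.get(eco, 1.0))
        ecc_vectors[source] = ecc_vectors.get(source, 0.0) + w * scaled
    return ecc_vectors, eco_vectors


class PipelineResult(dict):
    """Summary mapping with attribute-style helpers left to callers."""


def run_pipeline(
    config: RunConfig,
    outdir: str | Path | None = None,
    n_islands: int = 4,
    scenario: str = "mixed",
    shape: tuple[int, int] = (64, 80),
    n_occurrences: int = 150,
) -> PipelineResult:
    """Run every stage on a synthetic archipelago; return the summary.

    When ``outdir`` is given, rasters, tables and the summary JSON are
    written beneath it.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- simulate -----------------------------------------------------------
    stacks, occs, truth = synthetic_landscape.make_archipelago(
        seed=config.seed,
        n_islands=n_islands,
        scenario=scenario,
        shape=shape,
        n_occurrences=n_occurrences,
    )
    islands = sorted(stacks)
    if out is not None:
        write_simulation(out, stacks, occs, truth)

    # --- niche-model ensembles, projected to every island -------------------
    ensembles: dict[tuple[str, str], dict[str, enm.SuitabilityEnsemble]] = {}
    for i, occ in enumerate(sorted(occs, key=lambda o: (o.island_id, o.ecomorph))):
        cfg = replace(config, seed=_derived_seed(config.seed, 1, i))
        ensembles[(occ.island_id, occ.ecomorph)] = enm.fit_ensemble(
            occ, stacks[occ.island_id], cfg, projections=stacks
        )

    own_maps: dict[str, dict[str, GridRaster]] = {isl: {} for isl in islands}
    auc_rows = []
    for (island, eco), per_target in ensembles.items():
        ens = per_target[island]
        own_maps[island][eco] = ens.mean_map
        auc_rows.append(
            {"island": island, "ecomorph": eco, "mean_test_auc": ens.mean_test_auc}
        )
    auc_table = pd.DataFrame(auc_rows).sort_values(["island", "ecomorph"]).reset_index(drop=True)

    # --- per-island ECC ------------------------------------------------------
    ecc_maps = {
        isl: community.ecc(own_maps[isl], weights=config.ecc_weights) for isl in islands
    }
    if out is not None:
        (out / "ecc").mkdir(exist_ok=True)
        for isl in islands:
            write_raster(ecc_maps[isl].raster, out / "ecc" / f"{isl}.asc")
        (out / "enm").mkdir(exist_ok=True)
        for (island, eco), per_target in ensembles.items():
            d = out / "enm" / island
            d.mkdir(exist_ok=True)
            write_raster(per_target[island].mean_map, d / f"{eco}.asc")
        auc_table.to_csv(out / "enm" / "test_aucs.csv", index=False)

    # --- cross-fitted overlap ------------------------------------------------
    ecc_vectors, eco_vectors = cross_fitted_surfaces(
        ensembles, islands, weights=config.ecc_weights
    )
    overlap = community.overlap_report(ecc_vectors, eco_vectors)
    if out is not None:
        overlap.to_csv(out / "overlap.csv")

    # --- point extraction and pooled PCA -------------------------------------
    per_island_points = {
        isl: envstats.extract_points(stacks[isl], ecc_maps[isl]) for isl in islands
    }
    pooled = pd.concat(per_island_points.values(), ignore_index=True)
    biopcs = envstats.pca_bioclim(pooled)
    offsets = {}
    start = 0
    for isl in islands:
        n = len(per_island_points[isl])
        offsets[isl] = (start, start + n)
        start += n

    # --- correlations and model selection per island --------------------------
    corr_rows = []
    tables: dict[str, model_selection.SelectionTable] = {}
    averaged: dict[str, pd.DataFrame] = {}
    dependence: dict[str, envstats.ElevationDependence] = {}
    for j, isl in enumerate(islands):
        lo, hi = offsets[isl]
        scores = biopcs.retained_scores.iloc[lo:hi].reset_index(drop=True)
        pts = per_island_points[isl].reset_index(drop=True)
        island_biopcs = envstats.BioPCResult(
            loadings=biopcs.loadings,
            eigenvalues=biopcs.eigenvalues,
            retained=biopcs.retained,
            scores=biopcs.scores.iloc[lo:hi].reset_index(drop=True),
        )
        dep = envstats.classify_elevation_dependence(
            island_biopcs,
            pts["elevation"].to_numpy(),
            threshold=config.elevation_dependence_threshold,
        )
        dependence[isl] = dep
        corr = envstats.correlation_pipeline(
            ecc_maps[isl], stacks[isl], config,
            seed=_derived_seed(config.seed, 2, j),
            points=pts, biopcs=island_biopcs,
        )
        corr_rows.append(
            {
                "island": isl,
                "pearson_R": corr.pearson_R,
                "slope": corr.slope,
                "intercept": corr.intercept,
                "spearman_r": corr.spearman_r,
                "p_value": corr.p_value,
                "n_reduced": corr.n,
            }
        )
        table = model_selection.select_for_island(
            pts, scores, dep.dependent, dep.independent, dep.all_dependent
        )
        tables[isl] = table
        if table.averaging_applied and table.single_best is None:
            averaged[isl] = model_selection.model_average(table)
    corr_table = pd.DataFrame(corr_rows)
    report = model_selection.island_report(tables)
    if out is not None:
        corr_table.to_csv(out / "correlations.csv", index=False)
        msdir = out / "model_selection"
        msdir.mkdir(exist_ok=True)
        report.to_csv(msdir / "report.csv")
        for isl, t in tables.items():
            t.as_frame().to_csv(msdir / f"{isl}_table.csv", index=False)
        for isl, avg in averaged.items():
            avg.to_csv(msdir / f"{isl}_averaged.csv")

    # --- traits ---------------------------------------------------------------
    elevations = {isl: stacks[isl].elevation for isl in islands}
    ctable = traits.constraint_table(own_maps, elevations)
    trait_r, trait_p, ctable = traits.trait_correlation(
        ctable,
        n_permutations=max(config.n_permutations, 1000),
        seed=_derived_seed(config.seed, 3),
    )
    if out is not None:
        tdir = out / "traits"
        tdir.mkdir(exist_ok=True)
        ctable.to_csv(tdir / "constraints.csv", index=False)
        write_json(
            {"r": trait_r, "p": trait_p, "n": int((~ctable["excluded"]).sum())},
            tdir / "trait_correlation.json",
        )

    # --- summary --------------------------------------------------------------
    elev_weight = {}
    for isl, t in tables.items():
        elev_weight[isl] = float(
            sum(m.weight for m in t.models if "elevation" in m.predictors)
        )
    summary = PipelineResult(
        {
            "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
            "scenario": scenario,
            "islands": {
                isl: {
                    "scenario": truth.scenario(isl),
                    "n_valid_cells": int(stacks[isl].n_valid),
                    "ecc_min": float(ecc_maps[isl].raster.masked_values().min()),
                    "ecc_max": float(ecc_maps[isl].raster.masked_values().max()),
                    "mean_test_auc": float(
                        auc_table.loc[auc_table["island"] == isl, "mean_test_auc"].mean()
                    ),
                    "pearson_R": corr_table.set_index("island").loc[isl, "pearson_R"],
                    "spearman_r": corr_table.set_index("island").loc[isl, "spearman_r"],
                    "p_value": corr_table.set_index("island").loc[isl, "p_value"],
                    "n_reduced": int(corr_table.set_index("island").loc[isl, "n_reduced"]),
                    "best_model": tables[isl].models[0].name,
                    "best_model_weight": tables[isl].models[0].weight,
                    "elevation_models_weight": elev_weight[isl],
                    "biopcs_retained": int(biopcs.retained),
                    "elevation_dependent_biopcs": dependence[isl].dependent,
                }
                for isl in islands
            },
            "overlap_ecc": {
                pair: float(overlap.loc[pair, "ECC"]) for pair in overlap.index
            },
            "trait_correlation": {
                "r": float(trait_r),
                "p": float(trait_p),
                "n": int((~ctable["excluded"]).sum()),
            },
        }
    )
    if out is not None:
        write_json(summary, out / "summary.json")
    return summary


def write_simulation(
    out: Path,
    stacks: dict[str, EnvStack],
    occs: list[OccurrenceSet],
    truth: synthetic_landscape.SyntheticTruth,
) -> None:
    """Write rasters, occurrence CSV and truth JSON for a simulated archipelago."""
    out.mkdir(parents=True, exist_ok=True)
    for isl, stack in sorted(stacks.items()):
        d = out / "islands" / isl
        d.mkdir(parents=True, exist_ok=True)
        for name, layer in stack.layers.items():
            write_raster(layer, d / f"{name}.asc")
    write_occurrences(
        sorted(occs, key=lambda o: (o.island_id, o.ecomorph)), stacks, out / "occurrences.csv"
    )
    write_json(truth.to_jsonable(), out / "truth.json")
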