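"""Synthetic island landscapes with known ground truth.

Generates elliptical islands with Gaussian-peak topography, climate layers
that are either elevation-coupled (lapse-rate linear function of elevation
plus noise) or elevation-independent (smoothed Gaussian random fields), and
per-ecomorph occurrence samples drawn from known suitability surfaces.
Because the generating truth is known, every downstream stage — niche model
fitting, community-completeness mapping, overlap, correlation and trait
analysis — can be tested for parameter recovery without any external data.

Two island archetypes are supported:

* ``mountain`` — suitability is a Gaussian function of elevation whose
  optimum decreases with the ecomorph's body-mass rank (small ecomorphs
  peak high); climate includes elevation-coupled temperature layers.
* ``flat-climate`` — suitability depends only on an elevation-independent
  climate layer, and the temperature layers are decoupled from elevation
  as well (low, elevation-independent temperature ranges).  This island
  hosts four ecomorphs instead of six.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_formats import EnvStack, GridRaster, OccurrenceSet

logger = logging.getLogger("eccpipe")

__all__ = [
    "MASS_ORDER",
    "EcomorphTruth",
    "ClimateLayerTruth",
    "SyntheticTruth",
    "default_truth",
    "make_island",
    "true_suitability",
    "sample_occurrences",
    "make_archipelago",
]

#: Fixed body-mass order, lightest first (rank 1 = smallest mass).
MASS_ORDER = ["twig", "grass-bush", "trunk", "trunk-crown", "trunk-ground", "crown-giant"]

#: Ecomorphs absent from the flat-climate island.
FLAT_ABSENT = ("grass-bush", "trunk")


@dataclass
class EcomorphTruth:
    """Generating parameters for one ecomorph's suitability surface."""

    mass_rank: int  # 1 (lightest) .. 6 (heaviest)
    optimum_m: float  # elevational optimum mu_e (m), mountain islands
    breadth_m: float  # elevational breadth sigma_e (m), > 0
    # flat-climate islands: Gaussian optimum/breadth in climate-driver units
    climate_optimum: float = 0.0
    climate_breadth: float = 1.0

    def __post_init__(self) -> None:
        if not self.breadth_m > 0 or not self.climate_breadth > 0:
            raise ValueError("suitability breadth must be > 0")
        if not 1 <= self.mass_rank <= 6:
            raise ValueError("mass_rank must lie in 1..6")


@dataclass
class ClimateLayerTruth:
    """Generating parameters for one climate layer."""

    elevation_coupled: bool
    lapse_slope: float = 0.0  # layer units per metre (coupled layers)
    intercept: float = 0.0
    noise_sd: float = 0.0
    field_sd: float = 1.0  # amplitude of the smoothed random field (uncoupled)
    smooth_sigma: float = 5.0  # Gaussian smoothing length, cells (uncoupled)
    nugget: float = 0.0  # fraction of field variance that is cell-level white noise
    # when generated as a random field, share this much correlation with the
    # named layer's field (keeps climate layers in realistic correlated pairs)
    correlate_with: str | None = None
    correlation: float = 0.0


@dataclass
class SyntheticTruth:
    """Full generating truth for an archipelago."""

    ecomorphs: dict[str, EcomorphTruth]
    climate: dict[str, ClimateLayerTruth]
    island_scenarios: dict[str, str] = field(default_factory=dict)
    # layers whose standardized sum drives flat-climate suitability (the "wet
    # axis" — the direction a correlation PCA of the pair retains)
    flat_driver_layers: tuple[str, ...] = ("precip", "moisture")

    def __post_init__(self) -> None:
        coupled = [c.elevation_coupled for c in self.climate.values()]
        if not (any(coupled) and not all(coupled)):
            raise ValueError(
                "climate truth needs at least one elevation-coupled and one "
                "elevation-independent layer"
            )
        for name, eco in self.ecomorphs.items():
            if not 1 <= eco.mass_rank <= 6:
                raise ValueError(f"ecomorph {name!r}: mass_rank out of 1..6")

    def scenario(self, island_id: str) -> str:
        return self.island_scenarios.get(island_id, "mountain")

    def to_jsonable(self) -> dict:
        return {
            "ecomorphs": {
                n: {
                    "mass_rank": e.mass_rank,
                    "optimum_m": e.optimum_m,
                    "breadth_m": e.breadth_m,
                    "climate_optimum": e.climate_optimum,
                    "climate_breadth": e.climate_breadth,
                }
                for n, e in self.ecomorphs.items()
            },
            "climate": {
                n: {
                    "elevation_coupled": c.elevation_coupled,
                    "lapse_slope": c.lapse_slope,
                    "intercept": c.intercept,
                    "noise_sd": c.noise_sd,
                }
                for n, c in self.climate.items()
            },
            "island_scenarios": dict(self.island_scenarios),
            "flat_driver_layers": list(self.flat_driver_layers),
        }


def default_truth(noise_scale: float = 1.0) -> SyntheticTruth:
    """The standard generating truth.

    Elevational optima decrease strictly with mass rank (the lightest
    ecomorph peaks highest) while breadths increase with it (the heaviest
    ecomorph is nearly unconstrained) — so lighter ecomorphs are restricted
    to high elevations, community completeness rises with elevation, and
    the trait analysis has a known negative target sign.  Two temperature
    layers follow linear lapse rates off
    elevation; precipitation and a moisture index are elevation-independent
    smoothed random fields.  ``noise_scale`` multiplies all noise standard
    deviations (0 gives deterministic climate given topography).
    """
    optima = {  # mu_e (m) strictly decreasing in mass rank
        "twig": 1050.0,
        "grass-bush": 850.0,
        "trunk": 680.0,
        "trunk-crown": 560.0,
        "trunk-ground": 380.0,
        "crown-giant": 0.0,
    }
    breadths = {  # sigma_e (m) increasing with mass rank: heavy = unconstrained
        "twig": 180.0,
        "grass-bush": 260.0,
        "trunk": 360.0,
        "trunk-crown": 480.0,
        "trunk-ground": 560.0,
        "crown-giant": 650.0,
    }
    # flat-climate scenario: optima/breadths along the wet axis, in units of
    # the standardized precip+moisture sum (sd about 1.9) — graded like the
    # elevational design so community completeness rises along the axis
    flat_optima = {
        "twig": 3.2,
        "grass-bush": 2.8,
        "trunk": 2.6,
        "trunk-crown": 2.4,
        "trunk-ground": 1.6,
        "crown-giant": -1.0,
    }
    flat_breadths = {
        "twig": 1.2,
        "grass-bush": 1.4,
        "trunk": 1.5,
        "trunk-crown": 1.6,
        "trunk-ground": 2.5,
        "crown-giant": 5.0,
    }
    ecomorphs = {
        name: EcomorphTruth(
            mass_rank=i + 1,
            optimum_m=optima[name],
            breadth_m=breadths[name],
            climate_optimum=flat_optima[name],
            climate_breadth=flat_breadths[name],
        )
        for i, name in enumerate(MASS_ORDER)
    }
    climate = {
        "temp_mean": ClimateLayerTruth(
            elevation_coupled=True, lapse_slope=-0.0065, intercept=26.0,
            noise_sd=0.25 * noise_scale, field_sd=1.5, smooth_sigma=5.0, nugget=0.3,
        ),
        "temp_range": ClimateLayerTruth(
            elevation_coupled=True, lapse_slope=0.004, intercept=8.0,
            noise_sd=0.3 * noise_scale, field_sd=1.0, smooth_sigma=5.0, nugget=0.3,
            correlate_with="temp_mean", correlation=0.85,
        ),
        "precip": ClimateLayerTruth(
            elevation_coupled=False, intercept=1600.0,
            field_sd=300.0 * max(noise_scale, 1e-12), smooth_sigma=5.0, nugget=0.3,
        ),
        "moisture": ClimateLayerTruth(
            elevation_coupled=False, intercept=0.0,
            field_sd=1.0 * max(noise_scale, 1e-12), smooth_sigma=5.0, nugget=0.3,
            correlate_with="precip", correlation=0.8,
        ),
    }
    return SyntheticTruth(ecomorphs=ecomorphs, climate=climate)


# ---------------------------------------------------------------------------
# island generation
# ---------------------------------------------------------------------------

def _random_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Smoothed Gaussian random field, standardized to unit variance."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def make_island(
    seed: int,
    shape: tuple[int, int] = (80, 100),
    n_peaks: int = 3,
    truth: SyntheticTruth | None = None,
    island_id: str = "island",
    scenario: str = "mountain",
    origin: tuple[float, float] = (0.0, 0.0),
    cell_size: float = 1000.0,
    peak_height: tuple[float, float] = (300.0, 520.0),
) -> EnvStack:
    """Generate one island: elliptical mask, Gaussian-peak topography, climate.

    In the ``flat-climate`` scenario the elevation-coupled climate layers of
    the truth are replaced by elevation-independent random fields (their
    lapse structure is severed), and peaks are lower.
    """
    rows, cols = shape
    if rows < 20 or cols < 20:
        raise ValueError("island shape must be at least 20x20 cells")
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if scenario not in {"mountain", "flat-climate"}:
        raise ValueError(f"unknown scenario {scenario!r}")
    truth = truth if truth is not None else default_truth()
    rng = np.random.default_rng(seed)

    rr, cc = np.mgrid[0:rows, 0:cols]
    rc, cc0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    mask = ((rr - rc) / (0.45 * rows)) ** 2 + ((cc - cc0) / (0.45 * cols)) ** 2 <= 1.0

    if scenario == "flat-climate":
        peak_height = (0.35 * peak_height[0], 0.35 * peak_height[1])
    elevation = np.zeros(shape)
    for _ in range(n_peaks):
        pr = rc + rng.uniform(-0.25, 0.25) * rows
        pc = cc0 + rng.uniform(-0.25, 0.25) * cols
        height = rng.uniform(*peak_height)
        width = rng.uniform(0.10, 0.20) * min(rows, cols)
        elevation += height * np.exp(-((rr - pr) ** 2 + (cc - pc) ** 2) / (2 * width**2))

    layers: dict[str, GridRaster] = {}
    geometry = dict(mask=mask, cell_size=cell_size, origin=origin)
    layers["elevation"] = GridRaster(values=elevation, name="elevation", **geometry)

    fields: dict[str, np.ndarray] = {}
    for name, spec in truth.climate.items():
        coupled = spec.elevation_coupled and scenario == "mountain"
        if coupled:
            values = spec.intercept + spec.lapse_slope * elevation
            if spec.noise_sd > 0:
                values = values + rng.normal(0.0, spec.noise_sd, size=shape)
        else:
            fld = _random_field(rng, shape, spec.smooth_sigma)
            if spec.correlate_with is not None and spec.correlate_with in fields:
                rho = spec.correlation
                fld = rho * fields[spec.correlate_with] + np.sqrt(1.0 - rho**2) * fld
            fields[name] = fld  # smooth part only: correlated pairs share it
            if spec.nugget > 0:
                fld = (
                    np.sqrt(1.0 - spec.nugget) * fld
                    + np.sqrt(spec.nugget) * rng.standard_normal(shape)
                )
            values = spec.intercept + spec.field_sd * fld
        layers[name] = GridRaster(values=values, name=name, **geometry)

    return EnvStack(layers=layers, island_id=island_id)


# ---------------------------------------------------------------------------
# suitability and occurrence sampling
# ---------------------------------------------------------------------------

def true_suitability(truth: SyntheticTruth, ecomorph: str, stack: EnvStack) -> GridRaster:
    """Ground-truth suitability surface: a Gaussian response along the driver.

    Mountain islands: ``s(x) = exp(-(elev(x) - mu_e)^2 / (2 sigma_e^2))``,
    in (0, 1], equal to 1 exactly where elevation hits the optimum.
    Flat-climate islands: the same functional form along the wet axis (the
    standardized sum of the flat-driver layers), an elevation-independent
    climate gradient.
    """
    if ecomorph not in truth.ecomorphs:
        raise KeyError(f"unknown ecomorph {ecomorph!r}")
    eco = truth.ecomorphs[ecomorph]
    if truth.scenario(stack.island_id) == "flat-climate":
        driver = np.zeros_like(stack.elevation.values)
        for name in truth.flat_driver_layers:
            spec = truth.climate[name]
            driver = driver + (stack.layers[name].values - spec.intercept) / spec.field_sd
        mu, sigma = eco.climate_optimum, eco.climate_breadth
    else:
        driver = stack.elevation.values
        mu, sigma = eco.optimum_m, eco.breadth_m
    s = np.exp(-((driver - mu) ** 2) / (2.0 * sigma**2))
    return stack.elevation.with_values(s, name=f"suitability:{ecomorph}")


def sample_occurrences(
    truth: SyntheticTruth,
    ecomorph: str,
    stack: EnvStack,
    n: int,
    seed: int,
) -> OccurrenceSet:
    """Draw ``n`` unique presence cells with probability ∝ true suitability.

    Sampling is without replacement at cell level, so presences are unique
    cells by construction (mirroring the deduplication applied to real
    locality records).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = true_suitability(truth, ecomorph, stack)
    cells = np.flatnonzero(stack.mask.ravel())
    if n > cells.size:
        raise ValueError(f"requested {n} occurrences but island has {cells.size} valid cells")
    weights = s.values.ravel()[cells]
    p = weights / weights.sum()
    rng = np.random.default_rng(seed)
    chosen = rng.choice(cells, size=n, replace=False, p=p)
    ncols = stack.mask.shape[1]
    pairs = sorted((int(i // ncols), int(i % ncols)) for i in chosen)
    return OccurrenceSet(ecomorph=ecomorph, island_id=stack.island_id, cells=pairs)


def make_archipelago(
    seed: int,
    n_islands: int = 4,
    scenario: str = "mixed",
    shape: tuple[int, int] = (80, 100),
    n_occurrences: int = 200,
    noise_scale: float = 1.0,
) -> tuple[dict[str, EnvStack], list[OccurrenceSet], SyntheticTruth]:
    """Generate an archipelago of islands with occurrences for each ecomorph.

    Scenarios: ``mountain`` (all islands mountainous, 6 ecomorphs each),
    ``flat-climate`` (all flat), ``mixed`` (the last island is flat-climate
    and hosts 4 ecomorphs — grass-bush and trunk are absent, mirroring the
    reduced ecomorph complement of a low-relief island).
    """
    if scenario not in {"mountain", "flat-climate", "mixed"}:
        raise ValueError(f"unknown scenario {scenario!r}")
    if n_islands < 1:
        raise ValueError("n_islands must be >= 1")
    truth = default_truth(noise_scale=noise_scale)
    root = np.random.SeedSequence(seed)
    island_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_islands)]
    occ_root = root.spawn(1)[0]

    stacks: dict[str, EnvStack] = {}
    occs: list[OccurrenceSet] = []
    extent_x = shape[1] * 1000.0
    occ_seq = iter(
        int(s.generate_state(1)[0] % 2**31) for s in occ_root.spawn(n_islands * len(MASS_ORDER))
    )
    for i in range(n_islands):
        island_id = f"island-{i + 1}"
        if scenario == "mountain":
            isl_scenario = "mountain"
        elif scenario == "flat-climate":
            isl_scenario = "flat-climate"
        else:
            isl_scenario = "flat-climate" if i == n_islands - 1 else "mountain"
        truth.island_scenarios[island_id] = isl_scenario
        stack = make_island(
            seed=island_seeds[i],
            shape=shape,
            truth=truth,
            island_id=island_id,
            scenario=isl_scenario,
            origin=(i * (extent_x + 50_000.0), 0.0),
        )
        stacks[island_id] = stack
        ecomorphs = [
            e for e in MASS_ORDER if not (isl_scenario == "flat-climate" and e in FLAT_ABSENT)
        ]
        for eco in ecomorphs:
            occs.append(
                sample_occurrences(truth, eco, stack, n=n_occurrences, seed=next(occ_seq))
            )
    return stacks, occs, truth
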