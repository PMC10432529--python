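"""Synthetic inputs with known ground truth for every pipeline stage.

Generates logistic growth curves with multiplicative lognormal noise,
fluorescence-dilution (CUSPER) cell populations with a planted division
distribution, toy stoichiometric models with controllable carbon-source
usability, and two-channel 16-bit microscopy scenes.  Each generator is
deterministic given its seed, and with noise switched off reproduces the
underlying closed forms exactly — which is what makes the downstream
estimators testable without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metabolic_overlap import MetabolicModel, Reaction

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CusperPopulation",
    "SyntheticImage",
    "CellSpec",
    "logistic",
    "gen_logistic_curve",
    "gen_cusper_population",
    "gen_toy_models",
    "gen_synthetic_image",
    "lognormal_factors",
]

#: Division counts are simulated at most to this value; deeper divisions are
#: unresolvable by the fluorescence-dilution readout (the working limit of
#: detection truncates at 4.5 anyway).
MAX_DIVISIONS = 8


@dataclass
class SimConfig:
    """Shared simulation settings; a fixed seed gives byte-identical output."""

    seed: int = 0
    noise_cv: float = 0.05
    n_replicates: int = 3
    time_grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 121.0, 24.0))

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass
class GroundTruth:
    """Planted, otherwise-unobservable truths for one simulated dataset."""

    true_mu: float | None = None
    true_K: float | None = None
    division_counts: np.ndarray | None = None
    model_carbon_sets: dict[str, frozenset[str]] | None = None
    cells: pd.DataFrame | None = None


@dataclass
class CusperPopulation:
    cells: pd.DataFrame
    background: np.ndarray
    truth: GroundTruth


def lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def logistic(t: np.ndarray, mu: float, K: float, N0: float) -> np.ndarray:
    """Logistic growth N(t) = K / (1 + ((K - N0)/N0) e^{-mu t})."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - N0) / N0) * np.exp(-mu * t))


def gen_logistic_curve(mu: float, K: float, N0: float, times: Sequence[float],
                       noise_cv: float = 0.0, seed: int = 0,
                       label: str = "sim") -> "GrowthCurve":
    """Logistic curve sampled on ``times`` with multiplicative lognormal noise."""
    from .growth_kinetics import GrowthCurve

    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if mu <= 0:
        raise ValueError("mu must be positive")
    if not 0 < N0 < K:
        raise ValueError("need 0 < N0 < K")
    rng = np.random.default_rng(seed)
    values = logistic(times, mu, K, N0) * lognormal_factors(rng, noise_cv, times.shape)
    return GrowthCurve(times=times, values=values, label=label, blank_corrected=True)


def gen_cusper_population(n_founders: int, division_pmf: Mapping[int, float],
                          gfp_mean: float = 5000.0, gfp_cv: float = 0.05,
                          bg_mean: float = 150.0, bg_cv: float = 0.2,
                          n_background: int = 200, seed: int = 0,
                          treatment: str = "sim", timepoint: float = 24.0,
                          replicate: int = 1) -> CusperPopulation:
    """Simulate a fluorescence-dilution population from a founder cohort.

    Each founder draws a division count ``k`` from ``division_pmf`` and
    leaves ``2**k`` descendants whose green intensity is the founder pool
    split in half at every division — ``gfp_mean / 2**k`` — perturbed by
    unit-mean lognormal noise of CV ``gfp_cv``.  Red intensity is constant
    (constitutive marker).  ``background`` holds draws from the image
    background distribution for limit-of-detection estimation.
    """
    ks = np.array(sorted(division_pmf), dtype=int)
    ps = np.array([division_pmf[int(k)] for k in ks], dtype=float)
    if np.any(ks < 0) or np.any(ks > MAX_DIVISIONS):
        raise ValueError(f"division counts must lie in 0..{MAX_DIVISIONS}")
    if np.any(ps < 0) or abs(ps.sum() - 1.0) > 1e-9:
        raise ValueError("division_pmf must be non-negative and sum to 1")
    if gfp_mean <= 0 or bg_mean <= 0:
        raise ValueError("intensities must be positive")

    rng = np.random.default_rng(seed)
    founder_k = rng.choice(ks, size=n_founders, p=ps)
    per_cell_k = np.repeat(founder_k, 2 ** founder_k)
    n_cells = per_cell_k.size
    signal = gfp_mean / 2.0 ** per_cell_k * lognormal_factors(rng, gfp_cv, n_cells)
    background = bg_mean * lognormal_factors(rng, bg_cv, n_background)

    fovs = np.arange(n_cells) // 100  # ~100 cells per field of view
    fov_bg = bg_mean * lognormal_factors(rng, bg_cv / 4 if bg_cv else 0.0, fovs.max() + 1)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "fov": fovs,
            "red_intensity": 3000.0 * lognormal_factors(rng, gfp_cv, n_cells),
            # measured intensity rides on the field-of-view background
            "green_intensity": signal + fov_bg[fovs],
            "bg_green": fov_bg[fovs],
            "timepoint": timepoint,
            "treatment": treatment,
            "replicate": replicate,
        }
    )
    truth = GroundTruth(division_counts=per_cell_k, cells=cells[["cell_id"]].assign(k=per_cell_k))
    return CusperPopulation(cells=cells, background=background, truth=truth)


def gen_toy_models(species_specs: Mapping[str, Sequence[str]],
                   inorganic_set: Sequence[str] = ("nh4", "pi", "so4"),
                   inorganic_demand: float = 0.1) -> list[MetabolicModel]:
    """Build one toy stoichiometric model per species.

    Every model shares the same exchange space (all inorganics plus the
    union of all species' carbon sources) but can transport and catabolise
    only its own usable carbons, so biomass flux is positive iff the medium
    supplies at least one usable carbon source and every inorganic.  The
    single lumped biomass reaction consumes one carbon-derived precursor
    plus ``inorganic_demand`` of each inorganic.
    """
    inorganics = sorted(set(inorganic_set))
    all_carbons = sorted({c for spec in species_specs.values() for c in spec})
    models = []
    for species, usable in species_specs.items():
        usable = sorted(set(usable))
        if not usable:
            raise ValueError(f"species {species!r} has an empty carbon set")
        mets = [f"{m}_e" for m in all_carbons + inorganics]
        mets += [f"{m}_c" for m in usable + inorganics]
        mets += ["precursor_c"]
        reactions: list[Reaction] = []
        exchanges: dict[str, str] = {}
        for m in all_carbons + inorganics:
            rid = f"EX_{m}_e"
            reactions.append(Reaction(rid, {f"{m}_e": -1.0}, lower_bound=0.0))
            exchanges[rid] = m
        for m in usable + inorganics:
            reactions.append(Reaction(f"T_{m}", {f"{m}_e": -1.0, f"{m}_c": 1.0}))
        for c in usable:
            reactions.append(Reaction(f"CAT_{c}", {f"{c}_c": -1.0, "precursor_c": 1.0}))
        biomass_stoich = {"precursor_c": -1.0}
        biomass_stoich.update({f"{i}_c": -inorganic_demand for i in inorganics})
        reactions.append(Reaction("BIOMASS", biomass_stoich))
        models.append(
            MetabolicModel(
                id=species,
                metabolites=mets,
                reactions=reactions,
                exchanges=exchanges,
                biomass_reaction="BIOMASS",
            )
        )
    return models


@dataclass
class CellSpec:
    """One planted cell: centre (row, col) px, semi-axes (µm), intensities."""

    center: tuple[float, float]
    semi_axes_um: tuple[float, float]
    red_intensity: float
    green_intensity: float


@dataclass
class SyntheticImage:
    red: np.ndarray
    green: np.ndarray
    pixel_size: float
    truth: pd.DataFrame  # centroid_r, centroid_c, area_um2, green_intensity, touches_edge


def gen_synthetic_image(cells: Sequence[CellSpec], shape: tuple[int, int] = (300, 300),
                        pixel_size: float = 0.045, bg_level: float = 200.0,
                        bg_sd: float = 20.0, green_bg_level: float = 150.0,
                        green_bg_sd: float = 10.0, seed: int = 0) -> SyntheticImage:
    """Render axis-aligned elliptical cells into a two-channel 16-bit scene.

    The red channel carries the segmentation signal (constant intensity per
    cell over Gaussian background); the green channel adds each cell's green
    intensity on its own background.  Ground truth records the realised
    pixel-mask area in µm² and whether the ellipse touches the image border.
    """
    from skimage.draw import ellipse

    rng = np.random.default_rng(seed)
    red = rng.normal(bg_level, bg_sd, shape)
    green = rng.normal(green_bg_level, green_bg_sd, shape)
    rows = []
    for spec in cells:
        r0, c0 = spec.center
        a_px = spec.semi_axes_um[0] / pixel_size
        b_px = spec.semi_axes_um[1] / pixel_size
        rr, cc = ellipse(r0, c0, a_px, b_px)
        inside = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        touches_edge = bool(
            (~inside).any()
            or (rr[inside].min() == 0) or (rr[inside].max() == shape[0] - 1)
            or (cc[inside].min() == 0) or (cc[inside].max() == shape[1] - 1)
        )
        rr, cc = rr[inside], cc[inside]
        red[rr, cc] = spec.red_intensity
        green[rr, cc] += spec.green_intensity
        rows.append(
            {
                "centroid_r": float(rr.mean()),
                "centroid_c": float(cc.mean()),
                "area_um2": rr.size * pixel_size**2,
                "green_intensity": spec.green_intensity,
                "touches_edge": touches_edge,
            }
        )
    truth = pd.DataFrame(rows, columns=["centroid_r", "centroid_c", "area_um2",
                                        "green_intensity", "touches_edge"])
    to_u16 = lambda a: np.clip(np.round(a), 0, 65535).astype(np.uint16)
    return SyntheticImage(red=to_u16(red), green=to_u16(green),
                          pixel_size=pixel_size, truth=truth)


# ---------------------------------------------------------------------------
# writers


def write_growth_csv(curves, path: str | Path) -> None:
    """Write curves as long-format CSV (time_h, well, value)."""
    frames = []
    for i, curve in enumerate(curves):
        frames.append(pd.DataFrame({"time_h": curve.times, "well": curve.label or f"W{i}",
                                    "value": curve.values}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_cells_csv(population: CusperPopulation, path: str | Path) -> None:
    population.cells.to_csv(path, index=False)


def write_image_tiff(image: SyntheticImage, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(path, np.stack([image.red, image.green]),
                     metadata={"axes": "CYX"})


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {}
    if truth.true_mu is not None:
        payload["true_mu"] = truth.true_mu
    if truth.true_K is not None:
        payload["true_K"] = truth.true_K
    if truth.division_counts is not None:
        payload["division_counts"] = np.asarray(truth.division_counts).tolist()
    if truth.model_carbon_sets is not None:
        payload["model_carbon_sets"] = {k: sorted(v) for k, v in truth.model_carbon_sets.items()}
    Path(path).write_text(json.dumps(payload, indent=1))
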