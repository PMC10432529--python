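"""Constraint-based metabolic overlap analysis.

Computes flux-balance growth of small stoichiometric models under defined
media, enumerates minimum-cardinality nutritional requirements (minimal
media), and derives the pairwise metabolic resource overlap (MRO) index:
the size of the intersection of two species' minimal nutrient requirements,
normalised by the mean (or, optionally, the minimum) requirement-set size.

Models follow the COBRA sign convention: exchange reactions export one
environment compound with stoichiometry -1, so uptake is a negative flux.
FBA solves a plain LP (HiGHS via :func:`scipy.optimize.linprog`); minimal
media solve a MILP with one binary indicator per medium compound and
enumerate alternative optima through integer cuts.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp
from scipy.sparse import csc_matrix

__all__ = [
    "Reaction",
    "MetabolicModel",
    "MediumSpec",
    "MinimalMediaResult",
    "MROResult",
    "ModelError",
    "NoGrowthError",
    "load_model",
    "save_model",
    "model_to_json",
    "model_from_json",
    "fba",
    "minimal_media",
    "minimal_media_bruteforce",
    "mro",
    "media_presets",
    "DEFAULT_INORGANICS",
    "MEDIA_CARBON_SOURCES",
]

#: Inorganic nutrients shared by every defined medium: ammonium, phosphate
#: and sulfate from the mineral base, magnesium, and the trace-element mix
#: lumped into a single pseudo-compound.
DEFAULT_INORGANICS: tuple[str, ...] = ("nh4", "pi", "so4", "mg2", "trace_elements")

#: Carbon compositions of the named in-silico media.  M5C mirrors the five
#: carbon sources assayed in vitro; L10C holds the ten most abundant
#: metabolites reported from arabidopsis leaves; L8C is the leaf composition
#: without citrate, alanine and threonine but with glucose.
MEDIA_CARBON_SOURCES: dict[str, tuple[str, ...]] = {
    "M5C": ("glucose", "fructose", "malate", "sorbitol", "methanol"),
    "L10C": (
        "fumarate",
        "sucrose",
        "aspartate",
        "malate",
        "citrate",
        "glutamate",
        "alanine",
        "fructose",
        "threonine",
        "methanol",
    ),
}
MEDIA_CARBON_SOURCES["L8C"] = tuple(
    c for c in MEDIA_CARBON_SOURCES["L10C"] if c not in {"citrate", "alanine", "threonine"}
) + ("glucose",)

_BIOMASS_PATTERN = re.compile(r"biomass|growth", re.IGNORECASE)
_GROWTH_TOL = 1e-6


class ModelError(ValueError):
    """Raised for structurally invalid models or model files."""


class NoGrowthError(RuntimeError):
    """Raised when an operation requires growth on the full medium but FBA is zero."""


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0


@dataclass
class MetabolicModel:
    """A stoichiometric model with explicit exchange reactions.

    ``exchanges`` maps an exchange-reaction id to the single environment
    compound it transports; ``biomass_reaction`` is the objective.
    """

    id: str
    metabolites: list[str]
    reactions: list[Reaction]
    exchanges: dict[str, str]
    biomass_reaction: str

    def __post_init__(self) -> None:
        rxn_ids = {r.id for r in self.reactions}
        if self.biomass_reaction not in rxn_ids:
            raise ModelError(f"biomass reaction {self.biomass_reaction!r} not in model {self.id!r}")
        missing = set(self.exchanges) - rxn_ids
        if missing:
            raise ModelError(f"exchange reactions absent from model: {sorted(missing)}")
        met_set = set(self.metabolites)
        for r in self.reactions:
            unknown = set(r.stoichiometry) - met_set
            if unknown:
                raise ModelError(f"reaction {r.id!r} references unknown metabolites {sorted(unknown)}")

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def stoichiometric_matrix(self) -> np.ndarray:
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, coeff in r.stoichiometry.items():
                S[met_index[m], j] = coeff
        return S

    def exchange_for_compound(self, compound: str) -> str | None:
        for rxn_id, comp in self.exchanges.items():
            if comp == compound:
                return rxn_id
        return None


@dataclass
class MediumSpec:
    """A named nutrient environment: carbon sources, inorganics, uptake cap."""

    name: str
    carbon_sources: frozenset[str]
    inorganics: frozenset[str]
    uptake_bound: float = 10.0

    def __post_init__(self) -> None:
        self.carbon_sources = frozenset(self.carbon_sources)
        self.inorganics = frozenset(self.inorganics)
        if self.carbon_sources & self.inorganics:
            raise ValueError("carbon sources and inorganics overlap")
        if self.uptake_bound <= 0:
            raise ValueError("uptake_bound must be positive")

    @property
    def compounds(self) -> frozenset[str]:
        return self.carbon_sources | self.inorganics


@dataclass
class MinimalMediaResult:
    species: str
    medium_name: str
    minimal_sets: list[frozenset[str]]
    growth_threshold: float
    carbon_sources: frozenset[str] = field(default_factory=frozenset)

    @property
    def union_requirements(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for s in self.minimal_sets:
            out |= s
        return out


@dataclass
class MROResult:
    pair: tuple[str, str]
    medium_name: str
    # explicit default because dataclasses would otherwise pick up type.mro
    mro: float = 0.0
    set_sizes: tuple[int, int, int] = (0, 0, 0)
    normalisation: str = "mean"
    carbon_only: bool = False


def media_presets(name: str, uptake_bound: float = 10.0,
                  inorganics: Iterable[str] = DEFAULT_INORGANICS) -> MediumSpec:
    """Return one of the named media (M5C, L8C, L10C) plus the mineral base.

    Other leaf-derived compositions (L13C/L18C/L26C) are not built in and
    must be supplied as an explicit :class:`MediumSpec`.
    """
    key = name.upper()
    if key not in MEDIA_CARBON_SOURCES:
        raise KeyError(
            f"unknown medium {name!r}; built-ins are {sorted(MEDIA_CARBON_SOURCES)}; "
            "other compositions require an explicit MediumSpec"
        )
    return MediumSpec(
        name=key,
        carbon_sources=frozenset(MEDIA_CARBON_SOURCES[key]),
        inorganics=frozenset(inorganics),
        uptake_bound=uptake_bound,
    )


# ---------------------------------------------------------------------------
# model IO


def model_to_json(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": list(model.metabolites),
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
            }
            for r in model.reactions
        ],
        "exchanges": dict(model.exchanges),
        "biomass_reaction": model.biomass_reaction,
    }


def model_from_json(payload: Mapping) -> MetabolicModel:
    try:
        return MetabolicModel(
            id=payload["id"],
            metabolites=list(payload["metabolites"]),
            reactions=[
                Reaction(
                    id=r["id"],
                    stoichiometry={m: float(v) for m, v in r["stoichiometry"].items()},
                    lower_bound=float(r.get("lower_bound", 0.0)),
                    upper_bound=float(r.get("upper_bound", 1000.0)),
                )
                for r in payload["reactions"]
            ],
            exchanges=dict(payload["exchanges"]),
            biomass_reaction=payload["biomass_reaction"],
        )
    except KeyError as exc:  # pragma: no cover - defensive
        raise ModelError(f"malformed model JSON: missing {exc}") from exc


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    mets = {m: cobra.Metabolite(m, compartment="e" if m.endswith("_e") else "c")
            for m in model.metabolites}
    for r in model.reactions:
        rxn = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cm.add_reactions([rxn])
        rxn.add_metabolites({mets[m]: v for m, v in r.stoichiometry.items()})
    cm.objective = model.biomass_reaction
    return cm


def _from_cobra(cm, biomass_pattern: re.Pattern = _BIOMASS_PATTERN) -> MetabolicModel:
    reactions = []
    exchanges: dict[str, str] = {}
    for rxn in cm.reactions:
        reactions.append(
            Reaction(
                id=rxn.id,
                stoichiometry={m.id: float(v) for m, v in rxn.metabolites.items()},
                lower_bound=float(rxn.lower_bound),
                upper_bound=float(rxn.upper_bound),
            )
        )
        if rxn.id.startswith("EX_") or rxn in cm.exchanges:
            mets = list(rxn.metabolites)
            if len(mets) == 1:
                compound = mets[0].id
                exchanges[rxn.id] = compound[:-2] if compound.endswith("_e") else compound
    biomass = [r.id for r in cm.reactions if biomass_pattern.search(r.id)]
    if not biomass:
        raise ModelError(
            f"no reaction id matching {biomass_pattern.pattern!r} in model {cm.id!r}"
        )
    return MetabolicModel(
        id=cm.id or "model",
        metabolites=[m.id for m in cm.metabolites],
        reactions=reactions,
        exchanges=exchanges,
        biomass_reaction=biomass[0],
    )


def save_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model as SBML L3/FBC (``.xml``/``.sbml``) or the JSON dialect."""
    path = Path(path)
    if path.suffix.lower() in {".xml", ".sbml"}:
        import cobra.io

        cobra.io.write_sbml_model(_to_cobra(model), str(path))
    else:
        path.write_text(json.dumps(model_to_json(model), indent=1))


def load_model(path: str | Path, biomass_pattern: str | None = None) -> MetabolicModel:
    """Read an SBML or JSON model; the biomass reaction is found by id pattern."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".xml", ".sbml"}:
        import cobra.io

        pattern = re.compile(biomass_pattern, re.IGNORECASE) if biomass_pattern else _BIOMASS_PATTERN
        return _from_cobra(cobra.io.read_sbml_model(str(path)), pattern)
    return model_from_json(json.loads(path.read_text()))


# ---------------------------------------------------------------------------
# FBA and minimal media


def _medium_bounds(model: MetabolicModel, medium: MediumSpec,
                   allowed: frozenset[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Flux bounds with uptake open only for ``allowed`` medium compounds."""
    allowed = medium.compounds if allowed is None else allowed
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    for j, r in enumerate(model.reactions):
        if r.id in model.exchanges:
            compound = model.exchanges[r.id]
            lb[j] = -medium.uptake_bound if compound in allowed else 0.0
            ub[j] = max(ub[j], 0.0)
    return lb, ub


def fba(model: MetabolicModel, medium: MediumSpec,
        allowed: frozenset[str] | None = None) -> float:
    """Maximise biomass flux under the medium; returns 0 for no feasible growth."""
    S = model.stoichiometric_matrix()
    lb, ub = _medium_bounds(model, medium, allowed)
    c = np.zeros(len(model.reactions))
    c[model.reaction_ids.index(model.biomass_reaction)] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=np.column_stack([lb, ub]),
                  method="highs")
    if res.status == 3:
        raise ModelError(f"FBA unbounded for model {model.id!r}: check exchange bounds")
    if not res.success:
        return 0.0
    return max(0.0, -res.fun)


def minimal_media(model: MetabolicModel, medium: MediumSpec,
                  threshold_fraction: float = 0.1,
                  max_alternatives: int = 50) -> MinimalMediaResult:
    """Enumerate minimum-cardinality compound sets that still support growth.

    A MILP opens/closes uptake of each medium compound through a binary
    indicator and minimises the number of open compounds subject to biomass
    flux >= ``threshold_fraction`` of the full-medium optimum.  All
    alternative optima of the same cardinality are enumerated by adding an
    integer cut per solution, up to ``max_alternatives``.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    max_growth = fba(model, medium)
    if max_growth <= _GROWTH_TOL:
        raise NoGrowthError(f"model {model.id!r} does not grow on medium {medium.name!r}")
    threshold = threshold_fraction * max_growth

    compounds = sorted(c for c in medium.compounds if model.exchange_for_compound(c))
    comp_index = {c: k for k, c in enumerate(compounds)}
    n_r, n_y = len(model.reactions), len(compounds)
    rxn_index = {rid: j for j, rid in enumerate(model.reaction_ids)}

    S = csc_matrix(model.stoichiometric_matrix())
    lb, ub = _medium_bounds(model, medium)
    # variables: [v (fluxes), y (compound indicators)]
    lower = np.concatenate([lb, np.zeros(n_y)])
    upper = np.concatenate([ub, np.ones(n_y)])
    integrality = np.concatenate([np.zeros(n_r), np.ones(n_y)])
    cost = np.concatenate([np.zeros(n_r), np.ones(n_y)])

    from scipy.sparse import csr_matrix, hstack

    S_padded = hstack([S, csr_matrix((S.shape[0], n_y))]).tocsr()
    constraints = [LinearConstraint(S_padded, 0.0, 0.0)]
    # uptake only when the indicator is open: v_ex + bound * y >= 0
    rows, cols, vals = [], [], []
    for k, compound in enumerate(compounds):
        j = rxn_index[model.exchange_for_compound(compound)]
        rows += [k, k]
        cols += [j, n_r + k]
        vals += [1.0, medium.uptake_bound]
    gate = csc_matrix((vals, (rows, cols)), shape=(n_y, n_r + n_y))
    constraints.append(LinearConstraint(gate, 0.0, np.inf))
    # biomass above threshold
    bio = np.zeros(n_r + n_y)
    bio[rxn_index[model.biomass_reaction]] = 1.0
    constraints.append(LinearConstraint(bio, threshold, np.inf))

    cuts: list[LinearConstraint] = []
    minimal_sets: list[frozenset[str]] = []
    best_size: int | None = None
    while len(minimal_sets) < max_alternatives:
        res = milp(c=cost, constraints=constraints + cuts,
                   bounds=Bounds(lower, upper), integrality=integrality)
        if not res.success:
            break
        y = res.x[n_r:]
        size = int(round(y.sum()))
        if best_size is None:
            best_size = size
        elif size > best_size:
            break
        chosen = frozenset(c for c in compounds if y[comp_index[c]] > 0.5)
        minimal_sets.append(chosen)
        cut = np.zeros(n_r + n_y)
        for c in chosen:
            cut[n_r + comp_index[c]] = 1.0
        cuts.append(LinearConstraint(cut, -np.inf, len(chosen) - 1))

    return MinimalMediaResult(
        species=model.id,
        medium_name=medium.name,
        minimal_sets=minimal_sets,
        growth_threshold=threshold,
        carbon_sources=frozenset(medium.carbon_sources),
    )


def minimal_media_bruteforce(model: MetabolicModel, medium: MediumSpec,
                             threshold_fraction: float = 0.1) -> MinimalMediaResult:
    """Exhaustive subset-search reference for :func:`minimal_media`.

    Enumerates every subset of the medium compounds in order of increasing
    size and keeps all smallest subsets that reach the growth threshold.
    Exponential in the compound count; intended for toy models only.
    """
    from itertools import combinations

    max_growth = fba(model, medium)
    if max_growth <= _GROWTH_TOL:
        raise NoGrowthError(f"model {model.id!r} does not grow on medium {medium.name!r}")
    threshold = threshold_fraction * max_growth
    compounds = sorted(c for c in medium.compounds if model.exchange_for_compound(c))
    minimal_sets: list[frozenset[str]] = []
    for size in range(1, len(compounds) + 1):
        for subset in combinations(compounds, size):
            if fba(model, medium, allowed=frozenset(subset)) >= threshold - 1e-9:
                minimal_sets.append(frozenset(subset))
        if minimal_sets:
            break
    return MinimalMediaResult(
        species=model.id,
        medium_name=medium.name,
        minimal_sets=minimal_sets,
        growth_threshold=threshold,
        carbon_sources=frozenset(medium.carbon_sources),
    )


def mro(res_a: MinimalMediaResult, res_b: MinimalMediaResult,
        carbon_only: bool = False, normalisation: str = "mean") -> MROResult:
    """Metabolic resource overlap between two species' requirement sets.

    With ``M_A``, ``M_B`` the unions over each species' alternative minimal
    media, ``mro = |M_A ∩ M_B| / ((|M_A| + |M_B|) / 2)`` (``normalisation=
    "mean"``) or ``|M_A ∩ M_B| / min(|M_A|, |M_B|)`` (``"min"``).
    ``carbon_only`` drops the shared inorganic base, which otherwise
    compresses the index towards 1.
    """
    if res_a.medium_name != res_b.medium_name:
        raise ValueError(
            f"MRO requires a common medium: {res_a.medium_name!r} vs {res_b.medium_name!r}"
        )
    if normalisation not in {"mean", "min"}:
        raise ValueError("normalisation must be 'mean' or 'min'")
    m_a, m_b = res_a.union_requirements, res_b.union_requirements
    if carbon_only:
        m_a &= res_a.carbon_sources
        m_b &= res_b.carbon_sources
    inter = m_a & m_b
    if not m_a or not m_b:
        value = 0.0
    elif normalisation == "mean":
        value = len(inter) / ((len(m_a) + len(m_b)) / 2.0)
    else:
        value = len(inter) / min(len(m_a), len(m_b))
    return MROResult(
        pair=(res_a.species, res_b.species),
        medium_name=res_a.medium_name,
        mro=value,
        set_sizes=(len(m_a), len(m_b), len(inter)),
        normalisation=normalisation,
        carbon_only=carbon_only,
    )
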