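"""Association statistics linking resource overlap, phylogeny and competition.

Pearson correlations, ordinary least-squares regressions with Type-I
eta-squared effect sizes, Gamma-family log-link GLMs with deviance-based
pseudo-R², and patristic (branch-length) phylogenetic distances from a
newick tree.  Regressions delegate to statsmodels; patristic distances to
dendropy.

The packaged fixtures ``table1_pd.csv`` (phylogenetic distances of six
phyllosphere strains to the focal strain Pantoea eucalypti 299R) and
``table2_metrics.csv`` (carbon-profile dissimilarities, MRO indices under
several media, and competition scores for the same six strains) let the
headline correlations be recomputed without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "PhyloDistances",
    "AssociationResult",
    "patristic_distances",
    "pearson",
    "fit_linear",
    "fit_gamma_glm",
    "load_reference_tables",
]


@dataclass
class PhyloDistances:
    focal: str
    distances: pd.Series


@dataclass
class AssociationResult:
    model: str
    estimate: float | None = None
    ci: tuple[float, float] | None = None
    r_squared: float | None = None
    adj_r_squared: float | None = None
    pseudo_r_squared: float | None = None
    F: float | None = None
    df: tuple[float, float] | None = None
    p_value: float | None = None
    eta_squared: dict[str, float] = field(default_factory=dict)
    params: pd.Series | None = None
    conf_int: pd.DataFrame | None = None


def patristic_distances(tree: str | Path | dendropy.Tree, focal: str) -> PhyloDistances:
    """Sum of branch lengths along tip-to-tip paths from the focal strain."""
    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        source = Path(tree)
        if source.exists():
            t = dendropy.Tree.get(path=str(source), schema="newick")
        else:
            t = dendropy.Tree.get(data=str(tree), schema="newick")
    pdm = t.phylogenetic_distance_matrix()
    taxa = {taxon.label: taxon for taxon in t.taxon_namespace}
    if focal not in taxa:
        raise KeyError(f"focal strain {focal!r} not a tip of the tree")
    out = {}
    for label, taxon in taxa.items():
        if label == focal:
            continue
        d = pdm.patristic_distance(taxa[focal], taxon)
        if d is None or not np.isfinite(d):
            raise ValueError(f"missing branch lengths on path to {label!r}")
        out[label] = float(d)
    return PhyloDistances(focal=focal, distances=pd.Series(out).sort_index())


def pearson(x, y) -> AssociationResult:
    """Pearson correlation with the two-sided t-test on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return AssociationResult(model="pearson", estimate=float(res.statistic),
                             p_value=float(res.pvalue), df=(1.0, float(x.size - 2)))


def _eta_squared(fit) -> dict[str, float]:
    """Type-I (sequential) eta-squared per model term."""
    anova = sm.stats.anova_lm(fit, typ=1)
    ss_total = anova["sum_sq"].sum()
    return {
        term: float(row["sum_sq"] / ss_total)
        for term, row in anova.iterrows()
        if term != "Residual"
    }


def fit_linear(data: pd.DataFrame, response: str, predictors: list[str],
               interactions: bool = False) -> AssociationResult:
    """OLS regression with overall F, (adjusted) R², CIs and Type-I η²."""
    joiner = " * " if interactions else " + "
    formula = f"{response} ~ {joiner.join(predictors)}"
    fit = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("rank-deficient design matrix")
    slope = fit.params.iloc[1] if len(fit.params) > 1 else fit.params.iloc[0]
    ci = fit.conf_int()
    return AssociationResult(
        model=formula,
        estimate=float(slope),
        ci=(float(ci.iloc[1, 0]), float(ci.iloc[1, 1])) if len(fit.params) > 1 else None,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        F=float(fit.fvalue),
        df=(float(fit.df_model), float(fit.df_resid)),
        p_value=float(fit.f_pvalue),
        eta_squared=_eta_squared(fit),
        params=fit.params,
        conf_int=ci,
    )


def fit_gamma_glm(data: pd.DataFrame, response: str, predictors: list[str],
                  interactions: bool = False) -> AssociationResult:
    """Gamma GLM with log link; pseudo-R² = 1 - residual/null deviance."""
    if (data[response] <= 0).any():
        raise ValueError("Gamma GLM requires a strictly positive response")
    joiner = " * " if interactions else " + "
    formula = f"{response} ~ {joiner.join(predictors)}"
    fit = smf.glm(formula, data=data,
                  family=sm.families.Gamma(link=sm.families.links.Log())).fit()
    pseudo_r2 = 1.0 - fit.deviance / fit.null_deviance if fit.null_deviance > 0 else 0.0
    ci = fit.conf_int()
    slope = fit.params.iloc[1] if len(fit.params) > 1 else fit.params.iloc[0]
    return AssociationResult(
        model=formula,
        estimate=float(slope),
        ci=(float(ci.iloc[1, 0]), float(ci.iloc[1, 1])) if len(fit.params) > 1 else None,
        pseudo_r_squared=float(pseudo_r2),
        df=(float(fit.df_model), float(fit.df_resid)),
        params=fit.params,
        conf_int=ci,
    )


def load_reference_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Packaged reference tables: (phylogenetic distances, overlap metrics)."""
    base = resources.files("phyllocomp").joinpath("data")
    t1 = pd.read_csv(base.joinpath("table1_pd.csv"))
    t2 = pd.read_csv(base.joinpath("table2_metrics.csv"))
    return t1, t2
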