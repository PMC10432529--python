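"""Logistic growth-curve fitting and carbon-utilisation profiling.

Plate-reader curves are blank-corrected against carbon-free medium, fitted
to the logistic model N(t) = K / (1 + ((K - N0)/N0) e^{-mu t}), and the
fitted growth rate (mu) and carrying capacity (K) per strain x carbon
source are z-scored into a carbon-utilisation profile.  The Euclidean
distance between a focal strain's profile row and every other strain is the
carbon-profile dissimilarity used as an empirical proxy for niche overlap;
complete-linkage clustering of the same distance matrix groups strains by
resource use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist, squareform

from .synthetic_data import logistic

__all__ = [
    "GrowthCurve",
    "LogisticFit",
    "CarbonProfileMatrix",
    "DissimilarityVector",
    "blank_correct",
    "fit_logistic",
    "logistic_auc",
    "build_carbon_profile",
    "profile_dissimilarity",
    "read_plate_csv",
    "fits_to_frame",
]

logger = logging.getLogger(__name__)

#: Curves whose span never exceeds this fraction of the maximum observed
#: value are treated as no-growth and reported as non-converged fits.
_FLAT_TOL = 1e-9


@dataclass
class GrowthCurve:
    times: np.ndarray
    values: np.ndarray
    label: str = ""
    blank_corrected: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


@dataclass
class LogisticFit:
    mu: float
    K: float
    N0: float
    auc: float
    converged: bool
    residual_sse: float
    label: str = ""


@dataclass
class CarbonProfileMatrix:
    """Strain x (carbon, parameter) matrix of z-scores.

    Columns are scaled independently with the sample SD (ddof=1);
    zero-variance columns are dropped with a warning.  Non-growth cells are
    coded mu = K = 0 before scaling.
    """

    data: pd.DataFrame
    dropped_columns: list[str] = field(default_factory=list)
    scaling: str = "per-column z-score, sample SD (ddof=1)"


@dataclass
class DissimilarityVector:
    focal: str
    distances: pd.Series
    distance_matrix: pd.DataFrame
    linkage_matrix: np.ndarray


def blank_correct(curve: GrowthCurve, blank: GrowthCurve) -> GrowthCurve:
    """Subtract the carbon-free blank pointwise; negatives clip to zero.

    The blank is linearly interpolated onto the curve's time grid when the
    grids differ; extrapolation outside the blank's range is refused.
    """
    if curve.times.shape == blank.times.shape and np.allclose(curve.times, blank.times):
        blank_values = blank.values
    else:
        if curve.times.min() < blank.times.min() - 1e-9 or curve.times.max() > blank.times.max() + 1e-9:
            raise ValueError("blank does not cover the curve's time range")
        blank_values = np.interp(curve.times, blank.times, blank.values)
    corrected = np.clip(curve.values - blank_values, 0.0, None)
    return GrowthCurve(times=curve.times, values=corrected,
                       label=curve.label, blank_corrected=True)


def logistic_auc(mu: float, K: float, N0: float, t0: float, t1: float) -> float:
    """Analytic integral of the fitted logistic over [t0, t1].

    The antiderivative of K / (1 + A e^{-mu t}) is (K/mu) ln(A + e^{mu t}).
    Evaluated in log-space for numerical safety at large mu*t.
    """
    if K <= 0 or mu <= 0:
        return 0.0
    A = (K - N0) / N0
    term = lambda t: np.logaddexp(np.log(A), mu * t)
    return (K / mu) * (term(t1) - term(t0))


def _no_growth_fit(curve: GrowthCurve) -> LogisticFit:
    return LogisticFit(mu=0.0, K=0.0, N0=0.0, auc=0.0, converged=False,
                       residual_sse=float(np.sum(curve.values**2)), label=curve.label)


def fit_logistic(curve: GrowthCurve) -> LogisticFit:
    """Least-squares logistic fit returning mu, K, N0 and the model AUC.

    AUC is the analytic integral of the fitted curve over the observed
    interval, which is robust to sparse (24 h) sampling.  Flat or all-zero
    curves return a non-converged fit with mu = K = 0 rather than raising.
    Initialisation: K from the maximum value, N0 from the first positive
    value, mu from the log-slope of the rising segment; K is bounded above
    by twice the observed maximum.
    """
    if curve.times.size < 4:
        raise ValueError("need at least 4 points to fit a logistic")
    t, y = curve.times, curve.values
    ymax = float(y.max())
    if ymax <= _FLAT_TOL or (y.max() - y.min()) < 0.05 * ymax:
        return _no_growth_fit(curve)

    positive = y[y > 0]
    n0_init = float(positive[0]) if positive.size else ymax / 100.0
    n0_init = min(n0_init, 0.9 * ymax)
    rising = np.flatnonzero((y > 0.05 * ymax) & (y < 0.8 * ymax))
    if rising.size >= 2:
        with np.errstate(divide="ignore"):
            slope = np.polyfit(t[rising], np.log(np.maximum(y[rising], 1e-12)), 1)[0]
        mu_init = float(np.clip(slope, 1e-3, 1e2))
    else:
        mu_init = 1.0 / max(t[-1] - t[0], 1e-6)

    lower = [1e-6, ymax * 1e-3, ymax * 1e-9]
    upper = [1e3, 2.0 * ymax, ymax]
    p0 = np.clip([mu_init, ymax, n0_init], lower, upper)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(logistic, t, y, p0=p0, bounds=(lower, upper),
                                maxfev=20000, xtol=1e-12, ftol=1e-12)
    except RuntimeError:
        return _no_growth_fit(curve)
    mu, K, N0 = map(float, popt)
    resid = y - logistic(t, mu, K, N0)
    sse = float(resid @ resid)
    # reject fits that explain nothing beyond a flat mean
    tss = float(np.sum((y - y.mean()) ** 2))
    converged = bool(np.isfinite(sse) and (tss == 0 or sse < tss))
    if not converged:
        return _no_growth_fit(curve)
    return LogisticFit(mu=mu, K=K, N0=N0,
                       auc=logistic_auc(mu, K, N0, t[0], t[-1]),
                       converged=True, residual_sse=sse, label=curve.label)


def build_carbon_profile(fits: pd.DataFrame) -> CarbonProfileMatrix:
    """Assemble the z-scored strain x (carbon, parameter) profile matrix.

    ``fits`` needs columns strain, carbon_source, mu, K, converged.
    Non-converged (no-growth) conditions contribute mu = K = 0 before
    scaling; each (carbon, parameter) column is z-scored across strains.
    """
    required = {"strain", "carbon_source", "mu", "K", "converged"}
    if missing := required - set(fits.columns):
        raise ValueError(f"fits frame missing columns {sorted(missing)}")
    if fits["strain"].nunique() < 2:
        raise ValueError("need at least 2 strains to build a profile")
    work = fits.copy()
    work.loc[~work["converged"].astype(bool), ["mu", "K"]] = 0.0
    wide = work.pivot_table(index="strain", columns="carbon_source",
                            values=["mu", "K"], aggfunc="mean", fill_value=0.0)
    wide.columns = [f"{carbon}:{param}" for param, carbon in wide.columns]
    wide = wide.sort_index(axis=1)

    sd = wide.std(axis=0, ddof=1)
    dropped = sd.index[sd == 0].tolist()
    if dropped:
        logger.warning("dropping zero-variance profile columns: %s", dropped)
    kept = wide.drop(columns=dropped)
    z = (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=1)
    return CarbonProfileMatrix(data=z, dropped_columns=dropped)


def profile_dissimilarity(profile: CarbonProfileMatrix, focal: str) -> DissimilarityVector:
    """Euclidean distances from the focal strain plus complete-linkage tree."""
    data = profile.data
    if focal not in data.index:
        raise KeyError(f"focal strain {focal!r} not in profile")
    dist_condensed = pdist(data.values, metric="euclidean")
    dist = pd.DataFrame(squareform(dist_condensed), index=data.index, columns=data.index)
    merge = linkage(dist_condensed, method="complete")
    return DissimilarityVector(
        focal=focal,
        distances=dist.loc[focal].drop(focal),
        distance_matrix=dist,
        linkage_matrix=merge,
    )


def linkage_to_newick(linkage_matrix: np.ndarray, labels: Sequence[str]) -> str:
    """Serialise a SciPy linkage as a newick string (complete-linkage tree)."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage_matrix, list(labels))
    return str(tree).strip()


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Read long-format plate-reader CSV (time_h, well, strain, condition, value)."""
    frame = pd.read_csv(path)
    required = {"time_h", "well", "value"}
    if missing := required - set(frame.columns):
        raise ValueError(f"plate CSV missing columns {sorted(missing)}")
    return frame


def fits_to_frame(fits: Sequence[LogisticFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"label": f.label, "mu": f.mu, "K": f.K, "N0": f.N0, "auc": f.auc,
             "converged": f.converged, "residual_sse": f.residual_sse}
            for f in fits
        ]
    )
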