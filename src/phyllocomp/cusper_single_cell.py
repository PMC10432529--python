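"""Single-cell reproductive-success (CUSPER) pipeline.

A fluorescence-dilution bioreporter halves its green-fluorescent pool at
every cell division, so the reproductive success of cell n at time t is

    RS_{n,t} = log2( xbar_0 / x_{n,t} ),

with xbar_0 the mean background-corrected intensity of the population at
time zero.  Dim cells become indistinguishable from image background; the
limit of detection (LOD) is the RS value with a 5% probability of being
background noise (the lower 5% quantile of RS computed on background
readings), snapped down to the nearest division-bin edge.  Cells are binned
into RS_0..RS_4 on half-open unit intervals centred on whole divisions,
with everything at or beyond the LOD pooled into a censored RS_>4 class.

From the binned population structure the founder (immigrant) population is
reconstructed by down-weighting each division class by its clonal expansion
2^k, which also yields the fold increase of the population since
inoculation.  Structures are compared with Bray-Curtis dissimilarity and a
permutational multivariate ANOVA (PERMANOVA) with sequential (Type-I) sums
of squares on the distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "BIN_LABELS",
    "BIN_EDGES",
    "PermanovaResult",
    "background_correct",
    "reproductive_success",
    "lod_from_background",
    "bin_rs",
    "fractions_from_bins",
    "founder_reconstruction",
    "bray_curtis",
    "permanova",
]

BIN_LABELS = ["RS_0", "RS_1", "RS_2", "RS_3", "RS_4", "RS_>4"]
#: Half-open division bins: RS_k covers [k - 0.5, k + 0.5); RS_>4 is >= 4.5.
BIN_EDGES = np.array([0.5, 1.5, 2.5, 3.5, 4.5])

#: Floor for background-corrected intensities; cells dimmer than background
#: cannot be quantified and are flagged censored.
INTENSITY_FLOOR = 1.0

#: Cell count per replicate below which distribution estimates are flagged.
MIN_CELLS_WARN = 100


@dataclass
class PermanovaResult:
    factor: str
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    df: tuple[int, int]


def background_correct(cells: pd.DataFrame, green_col: str = "green_intensity",
                       bg_col: str = "bg_green", fov_col: str = "fov",
                       floor: float = INTENSITY_FLOOR) -> pd.DataFrame:
    """Subtract the per-field-of-view mean background from each cell.

    Results at or below zero are floored at ``floor`` (1 a.u.) and flagged
    ``floor_censored``: such cells are dimmer than background and hence at
    or beyond the limit of detection.
    """
    for col in (green_col, bg_col, fov_col):
        if col not in cells.columns:
            raise KeyError(f"cells frame lacks column {col!r}")
    if cells[bg_col].isna().any():
        bad = cells.loc[cells[bg_col].isna(), fov_col].unique()
        raise ValueError(f"missing background for field(s) of view {bad.tolist()}")
    out = cells.copy()
    fov_bg = cells.groupby(fov_col)[bg_col].transform("mean")
    corrected = cells[green_col] - fov_bg
    out["green_corrected"] = np.maximum(corrected, floor)
    out["floor_censored"] = corrected <= 0
    return out


def reproductive_success(x0_mean: float, x) -> np.ndarray:
    """RS = log2(xbar_0 / x): divisions since arrival encoded by dilution."""
    x = np.asarray(x, dtype=float)
    if x0_mean <= 0:
        raise ValueError("x0_mean must be positive")
    if np.any(x <= 0):
        raise ValueError("intensities must be positive")
    return np.log2(x0_mean / x)


def lod_from_background(bg_rs, alpha: float = 0.05, min_samples: int = 20,
                        snap_to_bin_edge: bool = False) -> float:
    """Limit of detection: the RS below which only ``alpha`` of background falls.

    Computed as the empirical ``alpha`` quantile (linear ECDF interpolation)
    of RS values derived from background intensities.  With
    ``snap_to_bin_edge`` the working LOD is truncated down to the nearest
    division-bin edge (x.5), so a raw quantile of e.g. 4.58 yields 4.5.
    """
    bg_rs = np.asarray(bg_rs, dtype=float)
    if bg_rs.size < min_samples:
        raise ValueError(f"need >= {min_samples} background RS values, got {bg_rs.size}")
    lod = float(np.quantile(bg_rs, alpha))
    if snap_to_bin_edge:
        lod = np.floor(lod - 0.5) + 0.5
    return lod


def bin_rs(rs_values, lod: float = 4.5) -> pd.DataFrame:
    """Assign each RS value to a division bin; >= LOD pools into RS_>4.

    Bins are half-open: RS_0 < 0.5 <= RS_1 < 1.5 <= RS_2 ... RS_4 < 4.5.
    Negative RS (cells brighter than the t0 mean) goes to RS_0.  Returns a
    frame with columns rs, bin, censored.
    """
    if not np.isclose((lod - 0.5) % 1.0, 0.0):
        raise ValueError("LOD must align with a bin edge (x.5)")
    rs = np.asarray(rs_values, dtype=float)
    idx = np.searchsorted(BIN_EDGES, rs, side="right")
    labels = np.array(BIN_LABELS, dtype=object)[idx]
    censored = rs >= lod
    labels[censored] = "RS_>4"
    n_negative = int((rs < 0).sum())
    frame = pd.DataFrame({"rs": rs, "bin": pd.Categorical(labels, categories=BIN_LABELS),
                          "censored": censored})
    frame.attrs["n_negative_rs"] = n_negative
    return frame


def fractions_from_bins(binned: pd.DataFrame) -> pd.Series:
    """Relative fraction of cells per RS bin (sums to 1)."""
    counts = binned["bin"].value_counts().reindex(BIN_LABELS, fill_value=0)
    if counts.sum() == 0:
        raise ValueError("empty distribution")
    return counts / counts.sum()


def founder_reconstruction(fractions: pd.Series | dict,
                           rs_gt4_divisions: int = 5) -> tuple[pd.Series, float]:
    """Recover founder-population fractions and the population fold increase.

    A cell observed after k divisions represents 2^-k of a founder, so the
    founder fraction of class k is g_k = f_k 2^-k / sum_j f_j 2^-j and the
    population has grown 1 / sum_j f_j 2^-j fold since inoculation.  The
    censored RS_>4 class is assigned ``rs_gt4_divisions`` (default 5, the
    class lower bound, giving a conservative fold increase).
    """
    f = pd.Series(fractions, dtype=float).reindex(BIN_LABELS, fill_value=0.0)
    if f.sum() <= 0:
        raise ValueError("empty distribution")
    f = f / f.sum()
    divisions = np.array([0, 1, 2, 3, 4, rs_gt4_divisions], dtype=float)
    weights = f.values * 2.0 ** (-divisions)
    total = weights.sum()
    g = pd.Series(weights / total, index=BIN_LABELS)
    return g, float(1.0 / total)


def bray_curtis(fractions: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity between composition rows."""
    X = np.asarray(fractions, dtype=float)
    if np.any(X < 0):
        raise ValueError("fractions must be non-negative")
    return squareform(pdist(X, metric="braycurtis"))


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def permanova(dist: np.ndarray, factors: pd.DataFrame,
              n_permutations: int = 999, seed: int = 0) -> list[PermanovaResult]:
    """Sequential (Type-I) PERMANOVA on a distance matrix.

    Fits factors in the column order of ``factors`` via the Gower-centred
    inner-product matrix G = -1/2 J D^2 J; the pseudo-F of each factor uses
    its sequential sum of squares tr(H_k G) - tr(H_{k-1} G) against the
    residual of the full model.  Significance comes from unrestricted
    permutation of sample labels: p = (1 + #{F* >= F_obs}) / (n_perm + 1).
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if len(factors) != n:
        raise ValueError("factor table length must match distance matrix")
    for col in factors.columns:
        counts = factors[col].value_counts()
        if len(counts) < 2:
            raise ValueError(f"factor {col!r} has fewer than 2 levels")
        if (counts < 2).any():
            raise ValueError(f"factor {col!r} has singleton groups")

    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = -0.5 * J @ (D**2) @ J
    ss_total = float(np.trace(G))

    # cumulative hat matrices: intercept, then each factor added in order
    designs = [np.ones((n, 1))]
    dfs = []
    for col in factors.columns:
        dummies = pd.get_dummies(factors[col], drop_first=True).to_numpy(dtype=float)
        dfs.append(dummies.shape[1])
        designs.append(np.hstack([designs[-1], dummies]))
    hats = [_hat(X) for X in designs]
    df_resid = n - designs[-1].shape[1]
    resid_proj = np.eye(n) - hats[-1]

    def factor_stats(Gmat: np.ndarray) -> tuple[np.ndarray, float]:
        traces = np.array([np.trace(H @ Gmat) for H in hats])
        ss = np.diff(traces)
        ss_res = float(np.trace(resid_proj @ Gmat))
        return ss, ss_res

    ss_obs, ss_res_obs = factor_stats(G)
    if ss_res_obs <= 1e-12 or ss_total <= 1e-12:
        # degenerate: no residual or no total variation
        return [
            PermanovaResult(factor=col, pseudo_F=0.0,
                            r_squared=0.0 if ss_total <= 1e-12 else ss_obs[k] / ss_total,
                            p_value=1.0, n_permutations=n_permutations,
                            df=(dfs[k], df_resid))
            for k, col in enumerate(factors.columns)
        ]
    f_obs = (ss_obs / np.array(dfs)) / (ss_res_obs / df_resid)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(dfs))
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ss_p, ss_res_p = factor_stats(Gp)
        if ss_res_p <= 1e-12:
            continue
        f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_resid)
        exceed += f_p >= f_obs - 1e-12
    p_values = (1.0 + exceed) / (n_permutations + 1.0)

    return [
        PermanovaResult(factor=col, pseudo_F=float(f_obs[k]),
                        r_squared=float(ss_obs[k] / ss_total),
                        p_value=float(p_values[k]), n_permutations=n_permutations,
                        df=(dfs[k], df_resid))
        for k, col in enumerate(factors.columns)
    ]
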