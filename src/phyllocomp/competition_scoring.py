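"""Competitive-ability score from mono-, intra- and inter-specific growth.

The score follows Chesson's coexistence framework: with mu_i the focal
strain's monoculture growth rate, a_ii = 1/K_intra the intraspecific
competition coefficient (focal vs a near-isogenic competitor) and
a_ij = 1/K_inter the interspecific coefficient,

    score = (mu_i - 1) / sqrt(a_ii * a_ij).

The numerator mixes a per-hour rate with the constant 1 and is implemented
exactly as printed; its sign therefore follows the sign of (mu_i - 1).
Scores within a cohort (one experimental context) are z-scored for
comparison across competitors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CompetitionInput",
    "CompetitionScore",
    "competition_coefficient",
    "competitive_score",
    "zscore_scores",
    "relative_auc_change",
]


@dataclass
class CompetitionInput:
    mu_mono: float
    K_intra: float
    K_inter: float
    auc_mono: float | None = None
    auc_co: float | None = None
    competitor: str = ""


@dataclass
class CompetitionScore:
    raw: float
    z: float | None
    competitor: str
    context: str = "in-vitro"


def competition_coefficient(K: float) -> float:
    """Competition coefficient, the reciprocal of the carrying capacity."""
    if K <= 0:
        raise ValueError("carrying capacity must be positive")
    return 1.0 / K


def competitive_score(inp: CompetitionInput) -> float:
    """(mu_i - 1) / sqrt(a_ii * a_ij) with a = 1/K."""
    a_ii = competition_coefficient(inp.K_intra)
    a_ij = competition_coefficient(inp.K_inter)
    return (inp.mu_mono - 1.0) / np.sqrt(a_ii * a_ij)


def zscore_scores(raw: Sequence[float]) -> np.ndarray:
    """Centre and rescale scores to mean 0, sample SD 1 within a cohort."""
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("need at least 2 scores to z-score")
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("scores have zero variance")
    return (raw - raw.mean()) / sd


def relative_auc_change(auc_co: float, auc_mono: float) -> float:
    """AUC with competitor over monoculture AUC; < 1 means suppression."""
    if auc_mono <= 0:
        raise ValueError("monoculture AUC must be positive")
    return auc_co / auc_mono
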