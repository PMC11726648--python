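"""Progressor dichotomization and the paired Wilcoxon signed-rank test.

A patient is a progressor for a measure and horizon when the score worsens
between baseline and follow-up: any increase for the motor measures
(extremity subscore, total motor score), any decrease for the cognitive
score.  A zero change is a non-progressor under both rules.

The signed-rank test here reports V, the sum of the ranks of the positive
differences (follow-up minus baseline), with zero differences dropped and
midranks for ties.  The two-sided p-value is exact — computed from the full
distribution over all 2^n sign assignments — for up to 25 nonzero
differences, and a normal approximation with tie and continuity corrections
beyond that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

MEASURES = ("extremity", "total_motor", "cognitive")
HORIZONS = ("Y1", "Y3")

#: worsening direction of the score change (follow-up minus baseline)
WORSENING_SIGN = {"extremity": +1, "total_motor": +1, "cognitive": -1}

EXACT_ENUMERATION_CUTOFF = 25


@dataclass(frozen=True)
class ProgressionLabel:
    """One patient's progressor status for one measure and horizon."""

    subject_id: str
    measure: str
    horizon: str
    delta: float
    progressor: bool


@dataclass(frozen=True)
class WilcoxonResult:
    """Paired signed-rank test summary (V = positive-rank sum)."""

    n_pairs: int
    n_nonzero: int
    v_statistic: float
    p_value: float
    method: str          # "exact", "normal_approx", or "degenerate"


def label_progressor(bl: float, fu: float, measure: str,
                     subject_id: str = "", horizon: str = "") -> ProgressionLabel:
    """Dichotomize one patient: worsening (strict) between baseline and follow-up."""
    if measure not in WORSENING_SIGN:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    delta = float(fu) - float(bl)
    progressor = (delta > 0) if WORSENING_SIGN[measure] > 0 else (delta < 0)
    return ProgressionLabel(subject_id=subject_id, measure=measure,
                            horizon=horizon, delta=delta, progressor=progressor)


def label_progressors(clinical: pd.DataFrame, measure: str, horizon: str) -> pd.DataFrame:
    """Label every patient with complete BL and follow-up scores.

    ``clinical`` is the long table (subject_id, visit, measure, value).
    Patients missing either visit are excluded with a logged reason.
    Returns a frame with columns subject_id, measure, horizon, delta,
    progressor.
    """
    if horizon not in HORIZONS:
        raise ValueError(f"horizon must be one of {HORIZONS}, got {horizon!r}")
    sub = clinical[clinical["measure"] == measure]
    wide = sub.pivot_table(index="subject_id", columns="visit", values="value",
                           aggfunc="first")
    rows = []
    for sid, row in wide.iterrows():
        bl, fu = row.get("BL"), row.get(horizon)
        if pd.isna(bl) or pd.isna(fu):
            logger.info("subject %s excluded for %s/%s: missing visit", sid, measure, horizon)
            continue
        lab = label_progressor(bl, fu, measure, subject_id=str(sid), horizon=horizon)
        rows.append((lab.subject_id, measure, horizon, lab.delta, lab.progressor))
    return pd.DataFrame(rows, columns=["subject_id", "measure", "horizon",
                                       "delta", "progressor"])


def _exact_signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the positive-rank sum over all 2^n sign assignments.

    Midranks are doubled to integers and the distribution built by
    convolution (each rank contributes a factor ``1 + x**r``), which
    enumerates all sign assignments without materializing them.

    Returns (support on the doubled-rank scale, counts).
    """
    doubled = np.round(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return np.arange(total + 1), counts


def wilcoxon_signed_rank(bl: np.ndarray, fu: np.ndarray,
                         exact_cutoff: int = EXACT_ENUMERATION_CUTOFF) -> WilcoxonResult:
    """Paired signed-rank test of follow-up vs. baseline.

    Differences ``d = fu - bl``; zeros are dropped (classic rule), the
    remaining |d| midranked, and V is the rank sum of the positive
    differences.  Two-sided p: ``min(1, 2*min(P(V <= v), P(V >= v)))``
    exactly for ``n_nonzero <= exact_cutoff``, otherwise by normal
    approximation with tie and continuity corrections.
    """
    bl = np.asarray(bl, dtype=float)
    fu = np.asarray(fu, dtype=float)
    if bl.shape != fu.shape or bl.ndim != 1:
        raise ValueError("bl and fu must be equal-length 1-D vectors")
    if bl.size < 5:
        raise ValueError("need at least 5 pairs")
    d = fu - bl
    nonzero = d != 0
    n_nz = int(nonzero.sum())
    if n_nz == 0:
        logger.warning("all paired differences are zero; degenerate test")
        return WilcoxonResult(n_pairs=bl.size, n_nonzero=0, v_statistic=0.0,
                              p_value=1.0, method="degenerate")
    dz = d[nonzero]
    ranks = sps.rankdata(np.abs(dz))
    v = float(ranks[dz > 0].sum())

    if n_nz <= exact_cutoff:
        support, counts = _exact_signed_rank_distribution(ranks)
        total = counts.sum()  # 2**n_nz
        v2 = int(round(2 * v))
        p_le = counts[: v2 + 1].sum() / total
        p_ge = counts[v2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mu = n_nz * (n_nz + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = (n_nz * (n_nz + 1) * (2 * n_nz + 1) / 24.0
               - (tie_counts**3 - tie_counts).sum() / 48.0)
        if var <= 0:
            p = 1.0
        else:
            # continuity correction of 0.5 toward the mean
            z = (v - mu - 0.5 * np.sign(v - mu)) / np.sqrt(var)
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "normal_approx"
    return WilcoxonResult(n_pairs=bl.size, n_nonzero=n_nz, v_statistic=v,
                          p_value=float(p), method=method)


def wilcoxon_table(clinical: pd.DataFrame, visits: tuple[str, str] = ("BL", "Y3"),
                   measures: tuple[str, ...] = MEASURES) -> pd.DataFrame:
    """Signed-rank comparison of two visits for each clinical measure."""
    rows = []
    for measure in measures:
        sub = clinical[clinical["measure"] == measure]
        wide = sub.pivot_table(index="subject_id", columns="visit", values="value",
                               aggfunc="first").dropna(subset=list(visits))
        res = wilcoxon_signed_rank(wide[visits[0]].to_numpy(),
                                   wide[visits[1]].to_numpy())
        rows.append((measure, visits[0], visits[1], res.n_pairs, res.n_nonzero,
                     res.v_statistic, res.p_value, res.method))
    return pd.DataFrame(rows, columns=["measure", "visit_a", "visit_b", "n_pairs",
                                       "n_nonzero", "v", "p_value", "method"])
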