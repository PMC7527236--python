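"""Gait taxonomy from girdle coupling, phase-frequency structure, and
speed-spatiotemporal relationships.

Quadrupedal gaits are defined by the left-right coupling pattern at each
girdle, on the folded [0.5, 1.0] phase scale: alternation (≈0.5) at both
girdles is a walk-trot; a phase-shifted girdle (≈0.75, the folded image of
the 0.25/0.75 gallop configurations) marks a gallop; synchronous hindlimbs
(≈1.0) with non-synchronous forelimbs a half-bound; synchrony at both
girdles a full-bound. The walk and trot are deliberately not distinguished.

Spatiotemporal structure: as locomotor speed rises, stride and stance times
shorten while stride length grows; these monotone relationships are
summarized by a Spearman rank correlation and an ordinary least-squares fit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, QuadgaitError, UndefinedStatisticError
from .interlimb import LimbPair, PhaseSample
from .io import StepCycle

__all__ = ["GaitLabel", "GaitBands", "SpeedRelation", "SlopeComparison",
           "classify_gait", "phase_frequency_table", "speed_relation",
           "compare_slopes", "SPEED_VARIABLES"]


class GaitLabel(str, enum.Enum):
    WALK_TROT = "walk_trot"
    GALLOP = "gallop"
    HALF_BOUND = "half_bound"
    FULL_BOUND = "full_bound"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class GaitBands:
    """Folded-phase bands for girdle coupling categories.

    Centered on the canonical patterns 0.5 (alternation), 0.75 (phase-
    shifted) and 1.0 (synchrony) with equal guard bands; configurable.
    """

    alternation_upper: float = 0.65   # alternation: [0.5, alternation_upper)
    synchrony_lower: float = 0.85     # synchrony: [synchrony_lower, 1.0]

    def category(self, folded: float) -> str:
        if not 0.5 <= folded <= 1.0:
            raise QuadgaitError(f"folded phase {folded} outside [0.5, 1.0]")
        if folded < self.alternation_upper:
            return "alternating"
        if folded >= self.synchrony_lower:
            return "synchronous"
        return "shifted"


def classify_gait(lr_hind_folded: float, lr_fore_folded: float,
                  bands: GaitBands = GaitBands()) -> GaitLabel:
    """Assign a gait label from the folded left-right coupling at each girdle.

    walk-trot: both girdles alternating; full-bound: both synchronous;
    half-bound: hindlimbs synchronous, forelimbs not; gallop: either girdle
    phase-shifted with the hindlimbs not synchronous; anything else is
    unclassified.
    """
    hind = bands.category(lr_hind_folded)
    fore = bands.category(lr_fore_folded)
    if hind == "alternating" and fore == "alternating":
        return GaitLabel.WALK_TROT
    if hind == "synchronous":
        return GaitLabel.FULL_BOUND if fore == "synchronous" else GaitLabel.HALF_BOUND
    if hind == "shifted" or fore == "shifted":
        return GaitLabel.GALLOP
    return GaitLabel.UNCLASSIFIED


def phase_frequency_table(samples: Sequence[PhaseSample], threshold_hz: float = 5.0
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts of steps at/below vs above a step-frequency threshold, per pair.

    The 5 Hz default marks the walk-trot → gallop transition zone. Returns
    ``(counts, polar)``: one count row per pair (n_at_or_below, n_above,
    n_total, pct_at_or_below) and the raw (phase, frequency) pairs for polar
    plotting. Samples without a finite frequency are excluded (logged via
    the counts' n_excluded column).
    """
    rows, polar = [], []
    by_pair: dict[LimbPair, list[PhaseSample]] = {}
    for s in samples:
        by_pair.setdefault(s.pair, []).append(s)
    for pair, group in by_pair.items():
        freqs = np.array([s.frequency for s in group], dtype=float)
        ok = np.isfinite(freqs)
        below = int(np.sum(freqs[ok] <= threshold_hz))
        total = int(np.sum(ok))
        rows.append({"pair": pair.value, "n_at_or_below": below,
                     "n_above": total - below, "n_total": total,
                     "n_excluded": int(np.sum(~ok)),
                     "pct_at_or_below": 100.0 * below / total if total else np.nan})
        for s, keep in zip(group, ok):
            if keep:
                polar.append({"pair": pair.value, "phase": s.raw_phase,
                              "frequency_hz": s.frequency,
                              "animal": s.animal_id, "timepoint": s.timepoint})
    return pd.DataFrame(rows), pd.DataFrame(polar)


SPEED_VARIABLES = {
    "stride_time": "stride_duration",
    "stance_time": "stance_duration",
    "swing_time": "swing_duration",
    "stride_length": "stride_length",
}


@dataclass(frozen=True)
class SpeedRelation:
    """Spearman + OLS summary of one spatiotemporal variable against speed."""

    variable: str
    spearman_rs: float
    spearman_p: float
    r_squared: float
    slope: float
    intercept: float
    slope_se: float
    n: int


def speed_relation(cycles: Sequence[StepCycle], variable: str) -> SpeedRelation:
    """Relationship between a spatiotemporal gait index and locomotor speed.

    Spearman rank correlation (average ranks on ties) plus an ordinary
    least-squares line of best fit (slope, intercept, R²). Cycles without a
    speed (event-only data) are skipped.
    """
    attr = SPEED_VARIABLES.get(variable)
    if attr is None:
        raise QuadgaitError(f"unknown variable {variable!r}; "
                            f"one of {sorted(SPEED_VARIABLES)}")
    pairs = [(c.speed, getattr(c, attr)) for c in cycles
             if c.speed is not None and getattr(c, attr) is not None]
    if len(pairs) < 3:
        raise InsufficientDataError("speed relation requires >= 3 cycles with speed")
    speed = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(speed) == 0:
        raise UndefinedStatisticError("correlation undefined at constant speed")
    rs = stats.spearmanr(speed, y)
    ols = stats.linregress(speed, y)
    return SpeedRelation(variable=variable, spearman_rs=float(rs.statistic),
                         spearman_p=float(rs.pvalue),
                         r_squared=float(ols.rvalue**2), slope=float(ols.slope),
                         intercept=float(ols.intercept),
                         slope_se=float(ols.stderr), n=speed.size)


@dataclass(frozen=True)
class SlopeComparison:
    t: float
    df: int
    p_value: float


def compare_slopes(rel1: SpeedRelation, rel2: SpeedRelation) -> SlopeComparison:
    """t test for equality of two independent regression slopes.

    ``t = (b1 − b2)/sqrt(SE1² + SE2²)`` on ``n1 + n2 − 4`` degrees of
    freedom, two-tailed. Swapping the arguments negates t.
    """
    se = np.hypot(rel1.slope_se, rel2.slope_se)
    if se == 0:
        raise UndefinedStatisticError("zero pooled slope standard error")
    t = (rel1.slope - rel2.slope) / se
    df = rel1.n + rel2.n - 4
    if df <= 0:
        raise InsufficientDataError("slope comparison requires n1 + n2 > 4")
    return SlopeComparison(t=float(t), df=int(df),
                           p_value=float(2.0 * stats.t.sf(abs(t), df)))
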