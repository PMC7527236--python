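"""Interlimb phase coupling, control-variability banding, and altered steps.

The coupling of a limb pair is the position of the paired limb's paw contact
within the reference limb's stride cycle, a circular value on [0, 1): 0.5 is
strict alternation, 0 (equivalently 1) is synchrony. To remove the
arbitrariness of which limb leads, circular phases are *folded* onto the
linear interval [0.5, 1.0] — mirror-image patterns such as 0.25 and 0.75
(both gallop configurations) coincide after folding.

Control variability is summarized by a band (pooled-control folded mean
± k·SD, default k = 2, clipped to [0.5, 1.0]); any step whose folded phase
falls outside the band is an *altered* step.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError, QuadgaitError, UndefinedStatisticError
from .io import Limb, LimbEventSeries, StepCycle

logger = logging.getLogger(__name__)

__all__ = [
    "LimbPair",
    "PhaseSample",
    "ControlBand",
    "fold_phase",
    "compute_phase",
    "compute_pair_phases",
    "build_control_band",
    "classify_steps",
    "coefficient_of_variation",
    "stepping_index",
]


class LimbPair(str, enum.Enum):
    """Limb pairings analyzed for temporal coupling."""

    LR_FORE = "LR_fore"          # left-right forelimbs
    LR_HIND = "LR_hind"          # left-right hindlimbs
    HLFL_IPSI = "HLFL_ipsi"      # homolateral hindlimb-forelimb (same side)
    HLFL_CONTRA = "HLFL_contra"  # diagonal hindlimb-forelimb


#: default (reference limb, paired limb) for each pair — right-limb reference
PAIR_LIMBS: dict[LimbPair, tuple[Limb, Limb]] = {
    LimbPair.LR_FORE: (Limb.RF, Limb.LF),
    LimbPair.LR_HIND: (Limb.RH, Limb.LH),
    LimbPair.HLFL_IPSI: (Limb.RH, Limb.RF),
    LimbPair.HLFL_CONTRA: (Limb.RH, Limb.LF),
}


def fold_phase(raw: float | np.ndarray) -> float | np.ndarray:
    """Fold a circular phase in [0, 1) onto the linear scale [0.5, 1.0].

    ``fold(x) = x if x >= 0.5 else 1 - x``; idempotent, and
    ``fold(x) == fold(1 - x)`` so lead-limb mirror patterns coincide.
    """
    raw = np.asarray(raw, dtype=float)
    folded = np.where(raw % 1.0 >= 0.5, raw % 1.0, 1.0 - raw % 1.0)
    # raw exactly 0 folds to 1.0 (synchrony), not 1 - 0 = 1.0 — consistent
    return float(folded) if folded.ndim == 0 else folded


@dataclass
class PhaseSample:
    """Circular coupling of one limb pair for one reference stride."""

    pair: LimbPair
    reference_limb: Limb
    raw_phase: float            # [0, 1)
    folded_phase: float         # [0.5, 1.0]
    frequency: float            # reference-limb step frequency, Hz
    speed: float | None = None  # cm/s
    altered: bool | None = None  # set by classify_steps
    animal_id: str = ""
    timepoint: str = ""
    pass_id: str = ""


@dataclass(frozen=True)
class ControlBand:
    """Pooled-control folded-phase mean ± k·SD, clipped to the folded scale."""

    pair: LimbPair
    mean_folded: float
    sd_folded: float
    k: float
    n: int

    @property
    def lower(self) -> float:
        return max(0.5, self.mean_folded - self.k * self.sd_folded)

    @property
    def upper(self) -> float:
        return min(1.0, self.mean_folded + self.k * self.sd_folded)

    def contains(self, folded: float | np.ndarray) -> np.ndarray:
        f = np.asarray(folded, dtype=float)
        return (f >= self.lower) & (f <= self.upper)


def compute_phase(reference_cycle: StepCycle, paired_series: LimbEventSeries,
                  pair: LimbPair, *, animal_id: str = "", timepoint: str = "",
                  pass_id: str = "", speed: float | None = None
                  ) -> PhaseSample | None:
    """Coupling phase of a paired limb within one reference stride.

    ``raw_phase = (t_paired - t_start) / stride_duration`` where ``t_paired``
    is the paired limb's first contact in the half-open stride window
    ``[start, start + stride)``. Returns ``None`` (logged) when the paired
    limb makes no contact in the window — a violation of 1:1 stepping,
    counted separately via the stepping index.
    """
    t0, t1 = reference_cycle.start_contact, reference_cycle.end_contact
    c = paired_series.contacts
    in_window = c[(c >= t0) & (c < t1)]
    if in_window.size == 0:
        logger.info("no %s contact in stride window [%g, %g); sample skipped",
                    paired_series.limb.value, t0, t1)
        return None
    raw = float((in_window[0] - t0) / reference_cycle.stride_duration)
    return PhaseSample(pair=pair, reference_limb=reference_cycle.limb,
                       raw_phase=raw, folded_phase=float(fold_phase(raw)),
                       frequency=reference_cycle.frequency,
                       speed=speed if speed is not None else reference_cycle.speed,
                       animal_id=animal_id, timepoint=timepoint, pass_id=pass_id)


def compute_pair_phases(reference_cycles: Sequence[StepCycle],
                        paired_series: LimbEventSeries, pair: LimbPair,
                        **meta) -> list[PhaseSample]:
    """Phase samples for every reference stride that has a paired contact."""
    out = []
    for cyc in reference_cycles:
        s = compute_phase(cyc, paired_series, pair, **meta)
        if s is not None:
            out.append(s)
    return out


def _folded(samples: Iterable[PhaseSample] | np.ndarray) -> np.ndarray:
    if isinstance(samples, np.ndarray):
        return samples.astype(float)
    return np.array([s.folded_phase for s in samples], dtype=float)


def build_control_band(samples: Sequence[PhaseSample] | np.ndarray,
                       pair: LimbPair | None = None, k: float = 2.0) -> ControlBand:
    """Band of normal variability from pooled control folded phases.

    Mean and sample (n−1) SD of the folded phases; the band is mean ± k·SD
    clipped to [0.5, 1.0]. Requires at least two samples.
    """
    folded = _folded(samples)
    if folded.size < 2:
        raise InsufficientDataError("control band requires >= 2 phase samples")
    if pair is None:
        pairs = {s.pair for s in samples}  # type: ignore[union-attr]
        if len(pairs) != 1:
            raise QuadgaitError("samples from multiple pairs; pass pair explicitly")
        pair = pairs.pop()
    return ControlBand(pair=pair, mean_folded=float(folded.mean()),
                       sd_folded=float(folded.std(ddof=1)), k=float(k),
                       n=int(folded.size))


def classify_steps(samples: Sequence[PhaseSample], band: ControlBand
                   ) -> tuple[list[PhaseSample], int, int]:
    """Flag altered steps against a control band; returns (samples, n_altered, n_total).

    A step is *altered* when its folded phase falls outside [lower, upper].
    The input samples are annotated in place and returned.
    """
    mismatched = [s for s in samples if s.pair != band.pair]
    if mismatched:
        raise QuadgaitError(
            f"band built for {band.pair.value} applied to {mismatched[0].pair.value} samples")
    n_altered = 0
    for s in samples:
        s.altered = not bool(band.contains(s.folded_phase))
        n_altered += s.altered
    return list(samples), n_altered, len(samples)


def coefficient_of_variation(folded: Sequence[float] | np.ndarray) -> float:
    """CoV (%) of folded phases for one animal-timepoint group: 100·SD/mean.

    Uses the sample (n−1) SD. The folded scale is bounded below by 0.5 so the
    mean cannot vanish. Requires at least two values.
    """
    x = np.asarray(folded, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("CoV requires >= 2 samples")
    return float(100.0 * x.std(ddof=1) / x.mean())


def coefficient_of_variation_by_group(samples: Sequence[PhaseSample]
                                      ) -> dict[tuple[str, str], float]:
    """Per (animal, timepoint) CoV of folded phase; groups with <2 samples skipped."""
    groups: dict[tuple[str, str], list[float]] = {}
    for s in samples:
        groups.setdefault((s.animal_id, s.timepoint), []).append(s.folded_phase)
    out = {}
    for key, vals in groups.items():
        if len(vals) < 2:
            logger.info("CoV group %s skipped (<2 samples)", key)
            continue
        out[key] = coefficient_of_variation(vals)
    return out


def stepping_index(fore_cycles: int, hind_cycles: int) -> float:
    """Quadrupedal stepping index: 100 × hindlimb / forelimb step counts.

    100 denotes strict 1:1 quadrupedal stepping.
    """
    if fore_cycles <= 0:
        raise UndefinedStatisticError("stepping index undefined with zero forelimb cycles")
    if hind_cycles <= 0:
        raise UndefinedStatisticError("stepping index undefined with zero hindlimb cycles")
    return 100.0 * hind_cycles / fore_cycles
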