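"""Intralimb and postural kinematics from 2-D marker coordinates.

The hindlimb is modelled as three segments (iliac crest–hip, hip–ankle,
ankle–toe) carrying two interior angles: the *proximal* angle at the hip
(between hip→iliac-crest and hip→ankle) and the *distal* angle at the ankle
(between ankle→hip and ankle→toe). Range of motion is the peak-to-trough
excursion of each angle over a stride; proximal–distal temporal coordination
is the circular phase lag between the two angles' peaks (0 = in-phase).

Postural measures: the base-of-support angle (external rotation of the hind
paw at initial contact relative to the body midline, from a three-point
shoulder-midpoint / groin / paw model) and the swim trunk angle (acute angle
between the iliac-crest→hip line and the water surface, from a four-point
model).

All angles are interior angles computed via arccos of normalized dot
products (clamped against rounding), in degrees, and are invariant under
global translation, rotation and uniform scaling of the coordinates.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import InsufficientDataError, MissingDataError, UndefinedStatisticError
from .io import Marker, MarkerTrack

logger = logging.getLogger(__name__)

__all__ = ["AngleTrace", "RangeOfMotion", "AngleName", "interior_angle",
           "joint_angles", "range_of_motion", "peak_timing_phase",
           "base_of_support_angle", "trunk_angle"]


class AngleName(str, enum.Enum):
    PROXIMAL = "proximal"
    DISTAL = "distal"


@dataclass
class AngleTrace:
    """Proximal/distal joint-angle time series over one stride."""

    stride_id: str
    times: np.ndarray          # s, within the stride interval
    proximal_deg: np.ndarray   # hip angle
    distal_deg: np.ndarray     # ankle angle

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.proximal_deg = np.asarray(self.proximal_deg, dtype=float)
        self.distal_deg = np.asarray(self.distal_deg, dtype=float)

    def angle(self, which: AngleName) -> np.ndarray:
        return self.proximal_deg if which is AngleName.PROXIMAL else self.distal_deg


@dataclass(frozen=True)
class RangeOfMotion:
    """Peak-to-trough excursion of one angle over one stride."""

    angle: AngleName
    peak_deg: float
    trough_deg: float

    @property
    def excursion_deg(self) -> float:
        return self.peak_deg - self.trough_deg


def interior_angle(vertex: np.ndarray, a: np.ndarray, b: np.ndarray) -> float | np.ndarray:
    """Interior angle at ``vertex`` between rays vertex→a and vertex→b, degrees.

    Vectorized over leading axes. Coincident points give NaN (degenerate ray).
    """
    vertex = np.asarray(vertex, dtype=float)
    u = np.asarray(a, dtype=float) - vertex
    v = np.asarray(b, dtype=float) - vertex
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.sum(u * v, axis=-1) / (nu * nv)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang = np.where((nu == 0) | (nv == 0), np.nan, ang)
    return float(ang) if ang.ndim == 0 else ang


def joint_angles(tracks: Mapping[Marker, MarkerTrack], t_start: float, t_stop: float,
                 stride_id: str = "") -> AngleTrace:
    """Per-frame proximal (hip) and distal (ankle) angles over a stride window.

    Requires iliac-crest, hip, ankle and toe tracks spanning the window.
    Frames at which a joint's defining points coincide have no defined angle
    and are dropped (logged).
    """
    needed = (Marker.ILIAC_CREST, Marker.HIP, Marker.ANKLE, Marker.TOE)
    missing = [m.value for m in needed if m not in tracks]
    if missing:
        raise MissingDataError(f"missing marker track(s): {', '.join(missing)}")
    grid = tracks[Marker.HIP]
    times = grid.times[(grid.times >= t_start - 1e-9) & (grid.times <= t_stop + 1e-9)]
    if times.size == 0:
        raise MissingDataError("no frames inside the stride window")
    pos = {m: np.atleast_2d(tracks[m].position_at(times)) for m in needed}
    proximal = interior_angle(pos[Marker.HIP], pos[Marker.ILIAC_CREST], pos[Marker.ANKLE])
    distal = interior_angle(pos[Marker.ANKLE], pos[Marker.HIP], pos[Marker.TOE])
    proximal = np.atleast_1d(proximal)
    distal = np.atleast_1d(distal)
    ok = np.isfinite(proximal) & np.isfinite(distal)
    if not np.all(ok):
        logger.info("stride %s: dropped %d frame(s) with coincident markers",
                    stride_id, int(np.sum(~ok)))
    return AngleTrace(stride_id, times[ok], proximal[ok], distal[ok])


def range_of_motion(trace: AngleTrace) -> tuple[RangeOfMotion, RangeOfMotion]:
    """Peak, trough and excursion of the proximal and distal angles."""
    if trace.times.size < 2:
        raise InsufficientDataError("range of motion requires >= 2 frames")
    out = []
    for name in (AngleName.PROXIMAL, AngleName.DISTAL):
        a = trace.angle(name)
        out.append(RangeOfMotion(name, float(a.max()), float(a.min())))
    return out[0], out[1]


def peak_timing_phase(trace: AngleTrace, stride_duration: float | None = None) -> float:
    """Circular phase lag of the distal peak relative to the proximal peak.

    ``phase = ((t_peak_distal − t_peak_proximal) / stride_duration) mod 1``;
    0 denotes in-phase proximal–distal coordination. Peaks are the global
    maxima within the stride (ties → earliest). A flat trace has no defined
    peak.
    """
    if trace.times.size == 0:
        raise InsufficientDataError("empty angle trace")
    if stride_duration is None:
        stride_duration = float(trace.times[-1] - trace.times[0])
    if stride_duration <= 0:
        raise UndefinedStatisticError("non-positive stride duration")
    for name in (AngleName.PROXIMAL, AngleName.DISTAL):
        if np.ptp(trace.angle(name)) == 0:
            raise UndefinedStatisticError(f"flat {name.value} trace has no peak")
    t_prox = trace.times[int(np.argmax(trace.proximal_deg))]
    t_dist = trace.times[int(np.argmax(trace.distal_deg))]
    return float(((t_dist - t_prox) / stride_duration) % 1.0)


def base_of_support_angle(shoulder_mid, groin, paw_at_contact) -> float:
    """Hind-paw external rotation at initial contact, degrees.

    Angle at the groin between the caudal extension of the body axis
    (shoulder-midpoint → groin, extended) and the groin → paw direction:
    0° places the paw on the midline extension, 90° perpendicular to it.
    """
    shoulder_mid = np.asarray(shoulder_mid, dtype=float)
    groin = np.asarray(groin, dtype=float)
    paw = np.asarray(paw_at_contact, dtype=float)
    u = groin - shoulder_mid   # body-axis direction, extended beyond the groin
    v = paw - groin
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UndefinedStatisticError("coincident points: base-of-support angle undefined")
    cosang = float(np.dot(u, v) / (nu * nv))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def trunk_angle(surface_left, surface_right, iliac_crest, hip) -> float:
    """Acute angle between the iliac-crest→hip line and the water surface, degrees.

    The surface line is defined by its two video extremes; the result is in
    [0°, 90°] (0° = body parallel to the surface) and is invariant under a
    common rotation of both lines.
    """
    u = np.asarray(surface_right, dtype=float) - np.asarray(surface_left, dtype=float)
    v = np.asarray(hip, dtype=float) - np.asarray(iliac_crest, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0:
        raise UndefinedStatisticError("degenerate water-surface line")
    if nv == 0:
        raise UndefinedStatisticError("coincident iliac crest and hip markers")
    cosang = abs(float(np.dot(u, v) / (nu * nv)))  # acute angle between lines
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
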