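"""Data model and I/O for footfall-event and marker-coordinate tables.

Units follow the conventions of rodent gait work: time in seconds, lengths in
cm, speeds in cm/s. A *stride* is paw contact to next contact of the same paw;
the *stance* phase runs from contact to the following lift, and the *swing*
phase completes the stride. Only complete strides (a contact pair with the
intervening lift) are analyzed; terminal partial cycles are dropped.

Event tables are long-format CSV with one row per contact or lift event.
Marker tables are long-format CSV with one row per (frame, marker).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EventValidationError, MissingDataError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "Limb",
    "Marker",
    "Task",
    "Condition",
    "TrialMetadata",
    "LimbEventSeries",
    "StepCycle",
    "MarkerTrack",
    "read_event_table",
    "write_event_table",
    "read_marker_table",
    "extract_step_cycles",
    "compute_speed",
    "EVENT_COLUMNS",
]


class Limb(str, enum.Enum):
    """The four limbs; L/R = left/right, F/H = fore/hind."""

    LF = "LF"
    RF = "RF"
    LH = "LH"
    RH = "RH"

    @property
    def is_fore(self) -> bool:
        return self in (Limb.LF, Limb.RF)

    @property
    def is_hind(self) -> bool:
        return not self.is_fore


class Marker(str, enum.Enum):
    """Anatomical landmarks digitized from video."""

    ILIAC_CREST = "iliac_crest"
    HIP = "hip"
    ANKLE = "ankle"
    TOE = "toe"
    SHOULDER_MID = "shoulder_mid"
    GROIN = "groin"
    PAW = "paw"
    NOSE = "nose"


class Task(str, enum.Enum):
    OVERGROUND = "overground"
    TREADMILL = "treadmill"
    EXPLORATORY = "exploratory"
    SWIM = "swim"


class Condition(str, enum.Enum):
    CONTROL = "control"
    DOX = "dox"


@dataclass(frozen=True)
class TrialMetadata:
    """Context labels for one recording pass."""

    surface: str = "coated"
    task: Task = Task.OVERGROUND
    condition: Condition = Condition.CONTROL


# logical name -> default CSV column
EVENT_COLUMNS: Mapping[str, str] = {
    "animal": "animal",
    "timepoint": "timepoint",
    "task": "task",
    "surface": "surface",
    "pass": "pass",
    "limb": "limb",
    "event_type": "event_type",
    "time": "time_s",
}

_REQUIRED_EVENT_FIELDS = ("animal", "timepoint", "pass", "limb", "event_type", "time")


@dataclass
class LimbEventSeries:
    """Ordered paw contact and lift times for one limb in one pass.

    Invariants (checked on construction): contacts strictly increasing, lifts
    strictly increasing, all times >= 0, and events interleave — every lift
    falls strictly between the contact that precedes it and the next contact
    (the last lift may follow the last contact).
    """

    animal_id: str
    timepoint: str
    pass_id: str
    limb: Limb
    contacts: np.ndarray
    lifts: np.ndarray
    task: str = Task.OVERGROUND.value
    surface: str = "coated"

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts, dtype=float)
        self.lifts = np.asarray(self.lifts, dtype=float)
        self.limb = Limb(self.limb)
        self._validate()

    def _validate(self) -> None:
        where = f"animal={self.animal_id} pass={self.pass_id} limb={self.limb.value}"
        for name, t in (("contacts", self.contacts), ("lifts", self.lifts)):
            if t.size and t.min() < 0:
                raise EventValidationError(f"negative {name[:-1]} time in {where}")
            if np.any(np.diff(t) <= 0):
                raise EventValidationError(f"{name} not strictly increasing in {where}")
        # interleaving: lift i must lie in (contact_i, contact_{i+1});
        # at most one trailing lift after the final contact
        c, l = self.contacts, self.lifts
        if l.size > c.size:
            raise EventValidationError(f"more lifts than contacts in {where}")
        for i, t in enumerate(l):
            if t <= c[i]:
                raise EventValidationError(
                    f"lift at {t:g}s precedes contact at {c[i]:g}s in {where}"
                )
            if i + 1 < c.size and t >= c[i + 1]:
                raise EventValidationError(
                    f"lift at {t:g}s does not interleave with contacts in {where}"
                )

    def shifted(self, dt: float) -> "LimbEventSeries":
        """Return a copy with all event times translated by ``dt`` seconds."""
        return replace(self, contacts=self.contacts + dt, lifts=self.lifts + dt)


@dataclass
class StepCycle:
    """One complete stride of one limb.

    ``stride_duration = stance_duration + swing_duration`` (within one frame
    interval); ``frequency = 1 / stride_duration``. ``stride_length`` and
    ``speed`` are populated only when marker tracks are available.
    """

    limb: Limb
    start_contact: float
    stride_duration: float
    stance_duration: float
    swing_duration: float
    frequency: float
    stride_length: float | None = None
    speed: float | None = None

    @property
    def end_contact(self) -> float:
        return self.start_contact + self.stride_duration

    @property
    def duty_cycle(self) -> float:
        return self.stance_duration / self.stride_duration


@dataclass
class MarkerTrack:
    """Planar coordinates of one marker sampled at a constant frame rate."""

    marker: Marker
    frame_rate: float
    xy: np.ndarray  # shape (n_frames, 2), cm
    t0: float = 0.0  # time of first frame, s

    def __post_init__(self) -> None:
        self.marker = Marker(self.marker)
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if self.xy.shape[1] != 2:
            raise SchemaError("marker track must have two coordinate columns")
        if self.frame_rate <= 0:
            raise SchemaError("frame_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.xy.shape[0]) / self.frame_rate

    def position_at(self, t: float | np.ndarray) -> np.ndarray:
        """Linearly interpolated (x, y) at time(s) ``t``.

        Raises :class:`MissingDataError` if ``t`` falls outside the track or a
        non-finite coordinate lies within the covering segment.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        times = self.times
        if np.any(t < times[0] - 1e-9) or np.any(t > times[-1] + 1e-9):
            raise MissingDataError(
                f"track for {self.marker.value} does not span requested times"
            )
        x = np.interp(t, times, self.xy[:, 0])
        y = np.interp(t, times, self.xy[:, 1])
        out = np.column_stack([x, y])
        if not np.all(np.isfinite(out)):
            raise MissingDataError(f"gap (non-finite samples) in {self.marker.value} track")
        return out[0] if out.shape[0] == 1 else out

    def shifted(self, dt: float) -> "MarkerTrack":
        return replace(self, t0=self.t0 + dt)


def _resolve_columns(df: pd.DataFrame, schema: Mapping[str, str] | None,
                     defaults: Mapping[str, str], required: Sequence[str]) -> dict:
    colmap = dict(defaults)
    if schema:
        colmap.update(schema)
    missing = [colmap[f] for f in required if colmap[f] not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return colmap


def read_event_table(path: str | Path, schema: Mapping[str, str] | None = None
                     ) -> list[LimbEventSeries]:
    """Read a long-format footfall event CSV into validated series.

    One :class:`LimbEventSeries` is returned per (animal, timepoint, pass,
    limb), with events sorted by time and interleaving validated. ``schema``
    remaps logical column names (see :data:`EVENT_COLUMNS`).
    """
    df = pd.read_csv(path)
    cm = _resolve_columns(df, schema, EVENT_COLUMNS, _REQUIRED_EVENT_FIELDS)
    bad = set(df[cm["event_type"]].unique()) - {"contact", "lift"}
    if bad:
        raise SchemaError(f"unknown event_type values: {sorted(bad)}")
    series: list[LimbEventSeries] = []
    keys = [cm["animal"], cm["timepoint"], cm["pass"], cm["limb"]]
    for (animal, timepoint, pass_id, limb), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values(cm["time"])
        contacts = grp.loc[grp[cm["event_type"]] == "contact", cm["time"]].to_numpy()
        lifts = grp.loc[grp[cm["event_type"]] == "lift", cm["time"]].to_numpy()
        kwargs = {}
        if cm["task"] in grp.columns:
            kwargs["task"] = str(grp[cm["task"]].iloc[0])
        if cm["surface"] in grp.columns:
            kwargs["surface"] = str(grp[cm["surface"]].iloc[0])
        series.append(
            LimbEventSeries(str(animal), str(timepoint), str(pass_id), Limb(str(limb)),
                            contacts, lifts, **kwargs)
        )
    return series


def write_event_table(series: Iterable[LimbEventSeries], path: str | Path) -> None:
    """Serialize series back to the long-format CSV read by :func:`read_event_table`."""
    rows = []
    for s in series:
        for kind, times in (("contact", s.contacts), ("lift", s.lifts)):
            for t in times:
                rows.append(
                    dict(animal=s.animal_id, timepoint=s.timepoint, task=s.task,
                         surface=s.surface, **{"pass": s.pass_id}, limb=s.limb.value,
                         event_type=kind, time_s=t)
                )
    pd.DataFrame(rows).sort_values(
        ["animal", "timepoint", "pass", "limb", "time_s"]
    ).to_csv(path, index=False)


def read_marker_table(path: str | Path, frame_rate: float,
                      schema: Mapping[str, str] | None = None
                      ) -> dict[tuple[str, str], dict[str, MarkerTrack]]:
    """Read a long-format marker CSV.

    Returns ``{(animal, pass): {marker_name: MarkerTrack}}``. The marker
    column may carry a per-limb suffix (e.g. ``paw_rh``); the base marker name
    must be one of :class:`Marker`. ``frame_rate`` applies to all tracks (it
    lives in the sidecar config, not the table).
    """
    defaults = {"animal": "animal", "pass": "pass", "frame": "frame",
                "marker": "marker", "x": "x_cm", "y": "y_cm"}
    df = pd.read_csv(path)
    cm = _resolve_columns(df, schema, defaults, list(defaults))
    out: dict[tuple[str, str], dict[str, MarkerTrack]] = {}
    for (animal, pass_id, marker), grp in df.groupby(
            [cm["animal"], cm["pass"], cm["marker"]], sort=True):
        grp = grp.sort_values(cm["frame"])
        base = str(marker).split("_")[0] if str(marker).startswith("paw_") else str(marker)
        track = MarkerTrack(Marker(base), frame_rate,
                            grp[[cm["x"], cm["y"]]].to_numpy(),
                            t0=float(grp[cm["frame"]].iloc[0]) / frame_rate)
        out.setdefault((str(animal), str(pass_id)), {})[str(marker)] = track
    return out


def extract_step_cycles(series: LimbEventSeries,
                        body_track: MarkerTrack | None = None,
                        paw_track: MarkerTrack | None = None) -> list[StepCycle]:
    """Extract complete strides from one limb's event series.

    One cycle per consecutive contact pair; the terminal partial cycle (final
    contact without a successor) is dropped. With fewer than two contacts an
    empty list is returned (logged, not an error). When ``body_track`` is
    given, :func:`compute_speed` populates speed and stride length.
    """
    c, l = series.contacts, series.lifts
    if c.size < 2:
        logger.info("pass %s limb %s: <2 contacts, no cycles",
                    series.pass_id, series.limb.value)
        return []
    cycles = []
    for i in range(c.size - 1):
        stride = c[i + 1] - c[i]
        in_window = l[(l > c[i]) & (l < c[i + 1])]
        if in_window.size != 1:  # guaranteed by validation, but be defensive
            logger.warning("pass %s limb %s: stride at %gs lacks a unique lift; skipped",
                           series.pass_id, series.limb.value, c[i])
            continue
        stance = in_window[0] - c[i]
        cyc = StepCycle(series.limb, float(c[i]), float(stride), float(stance),
                        float(stride - stance), float(1.0 / stride))
        if body_track is not None:
            compute_speed(cyc, body_track, paw_track)
        cycles.append(cyc)
    return cycles


def compute_speed(cycle: StepCycle, body_track: MarkerTrack,
                  paw_track: MarkerTrack | None = None) -> float:
    """Speed over one stride from the body reference marker, in cm/s.

    Speed is the horizontal (x) displacement of the body marker across the
    stride divided by the stride duration. Stride length is the horizontal
    displacement of the limb's paw marker between successive contacts
    (``paw_track``; falls back to the body marker when absent). Both are
    stored on the cycle; the speed is returned.
    """
    t0, t1 = cycle.start_contact, cycle.end_contact
    p0 = body_track.position_at(t0)
    p1 = body_track.position_at(t1)
    cycle.speed = float(abs(p1[0] - p0[0]) / cycle.stride_duration)
    paw = paw_track if paw_track is not None else body_track
    q0 = paw.position_at(t0)
    q1 = paw.position_at(t1)
    cycle.stride_length = float(abs(q1[0] - q0[0]))
    return cycle.speed
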