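"""Seeded synthetic gait generator.

Emulates the statistical structure of overground locomotor recordings so
that every pipeline stage is testable without video-derived data: per-limb
footfall event series whose pairwise coupling phases are von Mises-
distributed around alternation (0.5) or synchrony (0/1), stride times that
shrink and stride lengths that grow with speed (power-law stride-time
default), a duty cycle that falls with speed, body/paw marker tracks
consistent with the pass speed, and a configurable fraction of *disrupted*
strides whose left-limb phases are redrawn (uniformly on the circle, or
shifted by a quarter cycle).

The generator is deterministic given its seed: each (animal, pass) draws
from an independent substream derived from the scenario seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .errors import ConfigError
from .interlimb import LimbPair
from .io import Limb, LimbEventSeries, Marker, MarkerTrack
from .kinematics import AngleTrace

__all__ = ["GaitScenario", "DisruptionMode", "simulate_pass", "simulate_scenario",
           "simulate_angle_traces", "scenario_presets",
           "default_stride_time", "default_duty_cycle"]


class DisruptionMode(str, enum.Enum):
    UNIFORM_PHASE = "uniform_phase"
    SHIFTED_PHASE = "shifted_phase"


def default_stride_time(speed: np.ndarray | float) -> np.ndarray | float:
    """Power-law stride time t = 3.2 · v^(−0.55) s for v in cm/s.

    Over 20–100 cm/s this gives 0.62–0.25 s strides (1.6–3.9 Hz, keeping the
    walk-trot mass below the 5 Hz transition) and 12–25 cm stride lengths.
    """
    return 3.2 * np.asarray(speed, dtype=float) ** -0.55


def default_duty_cycle(speed: np.ndarray | float) -> np.ndarray | float:
    """Stance fraction falling linearly from 0.70 at 20 cm/s to 0.45 at 120 cm/s."""
    v = np.asarray(speed, dtype=float)
    return np.clip(0.70 + (v - 20.0) * (0.45 - 0.70) / 100.0, 0.45, 0.70)


_DEFAULT_MEANS: Mapping[LimbPair, float] = {
    LimbPair.LR_HIND: 0.5,    # left-right hindlimb alternation (LH rel. RH)
    LimbPair.LR_FORE: 0.5,    # left-right forelimb alternation (LF rel. RF)
    LimbPair.HLFL_IPSI: 0.5,  # homolateral out-of-phase (RF rel. RH)
}


@dataclass
class GaitScenario:
    """Parameters of one simulated recording condition.

    Pair phase means/concentrations control the von Mises coupling draws:
    left-right hindlimb and homolateral hindlimb-forelimb couplings are drawn
    relative to the right hindlimb reference, the left-right forelimb
    coupling relative to the right forelimb; the diagonal (contra) coupling
    emerges from their composition. ``concentration`` may be ``inf`` for a
    noiseless limit.
    """

    name: str = "scenario"
    n_animals: int = 6
    passes_per_animal: int = 8
    strides_per_pass: int = 12
    speed_range: tuple[float, float] = (20.0, 100.0)
    pair_phase_means: Mapping[LimbPair, float] = field(
        default_factory=lambda: dict(_DEFAULT_MEANS))
    concentration: Mapping[LimbPair, float] = field(
        default_factory=lambda: {p: 50.0 for p in _DEFAULT_MEANS})
    duty_cycle_fn: Callable = default_duty_cycle
    stride_time_fn: Callable = default_stride_time
    stride_jitter: float = 0.03   # lognormal sd of per-stride time, fraction
    disruption_rate: float = 0.0
    disruption_mode: DisruptionMode = DisruptionMode.UNIFORM_PHASE
    forelimbs: bool = True        # False for hindlimb-only (swim) conditions
    frame_rate: float = 200.0
    timepoint: str = "BL"
    task: str = "overground"
    surface: str = "coated"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.disruption_rate <= 1.0:
            raise ConfigError("disruption_rate must lie in [0, 1]")
        self.disruption_mode = DisruptionMode(self.disruption_mode)
        lo, hi = self.speed_range
        if not 0 < lo < hi:
            raise ConfigError("speed_range must be increasing and positive")
        if float(self.stride_time_fn(lo)) <= float(self.stride_time_fn(hi)):
            raise ConfigError("stride_time_fn must decrease over the speed range")
        for v in (lo, hi):
            d = float(self.duty_cycle_fn(v))
            if not 0.0 < d < 1.0:
                raise ConfigError(f"duty cycle {d} at {v} cm/s outside (0, 1)")

    def pass_rng(self, animal_index: int, pass_index: int) -> np.random.Generator:
        """Independent, deterministic substream for one (animal, pass)."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), animal_index, pass_index]))


def _draw_phase(rng: np.random.Generator, mean: float, kappa: float) -> float:
    if np.isinf(kappa):
        return float(mean % 1.0)
    return float((rng.vonmises(2.0 * np.pi * mean, kappa) / (2.0 * np.pi)) % 1.0)


def _lifts_from_contacts(contacts: np.ndarray, duty: float,
                         nominal_stride: float) -> np.ndarray:
    gaps = np.diff(contacts)
    lifts = contacts[:-1] + duty * gaps
    return np.append(lifts, contacts[-1] + duty * nominal_stride)


def _paw_track(contacts: np.ndarray, lifts: np.ndarray, x_at_contact: np.ndarray,
               grid: np.ndarray, frame_rate: float, y: float) -> MarkerTrack:
    # hold position through stance, advance linearly through swing
    knots_t = np.empty(2 * contacts.size)
    knots_x = np.empty_like(knots_t)
    knots_t[0::2] = contacts
    knots_t[1::2] = lifts
    knots_x[0::2] = x_at_contact
    knots_x[1::2] = x_at_contact
    x = np.interp(grid, knots_t, knots_x)
    return MarkerTrack(Marker.PAW, frame_rate,
                       np.column_stack([x, np.full_like(x, y)]), t0=float(grid[0]))


def simulate_pass(scenario: GaitScenario, animal_index: int, pass_index: int
                  ) -> tuple[dict[Limb, LimbEventSeries], dict[str, MarkerTrack]]:
    """Simulate one locomotor pass: four event series and marker tracks.

    The right hindlimb is the reference: its contacts fall at cumulative
    (jittered) stride times. Each other limb's contact within a reference
    stride is placed at a von Mises phase draw around that pair's mean. With
    probability ``disruption_rate`` a stride's left-limb phases are redrawn
    per the disruption mode. Lifts follow contacts at the speed-dependent
    duty-cycle fraction. The body (groin) marker advances at the pass speed;
    paw markers hold through stance and advance through swing.
    """
    rng = scenario.pass_rng(animal_index, pass_index)
    animal = f"A{animal_index + 1}"
    # pass ids embed the timepoint so they stay unique per animal when
    # conditions are pooled into one events/markers table
    pass_id = f"{scenario.timepoint}-P{pass_index + 1}"
    v = float(rng.uniform(*scenario.speed_range))
    t_nominal = float(scenario.stride_time_fn(v))
    duty = float(scenario.duty_cycle_fn(v))
    n = scenario.strides_per_pass
    strides = t_nominal * np.exp(rng.normal(0.0, scenario.stride_jitter, size=n))
    rh_contacts = 0.2 + np.concatenate([[0.0], np.cumsum(strides)])  # n+1 contacts

    means = scenario.pair_phase_means
    kappa = scenario.concentration
    lh, rf, lf = [], [], []
    for i in range(n + 1):
        stride_i = strides[i] if i < n else t_nominal
        ph_lh = _draw_phase(rng, means[LimbPair.LR_HIND], kappa[LimbPair.LR_HIND])
        ph_rf = _draw_phase(rng, means[LimbPair.HLFL_IPSI], kappa[LimbPair.HLFL_IPSI])
        ph_lf = _draw_phase(rng, means[LimbPair.LR_FORE], kappa[LimbPair.LR_FORE])
        if scenario.disruption_rate and rng.random() < scenario.disruption_rate:
            # the disrupted stride decouples the left limbs from their
            # right-side partners; the homolateral RH-RF coupling is spared
            if scenario.disruption_mode is DisruptionMode.UNIFORM_PHASE:
                ph_lh = float(rng.random())
                ph_lf = float(rng.random())
            else:
                ph_lh = (ph_lh + 0.25) % 1.0
                ph_lf = (ph_lf + 0.25) % 1.0
        lh.append(rh_contacts[i] + ph_lh * stride_i)
        rf.append(rh_contacts[i] + ph_rf * stride_i)
        # LF placed relative to the RF contact: left-right forelimb coupling
        # is drawn directly; diagonal RH-LF synchrony emerges from the two
        lf.append(rh_contacts[i] + (ph_rf + ph_lf) * stride_i)

    def _monotone(c: list[float]) -> np.ndarray:
        # composed offsets can exceed one stride under disruption; restore
        # temporal order without changing the step count
        out = np.sort(np.asarray(c, dtype=float))
        for j in range(1, out.size):
            if out[j] <= out[j - 1]:
                out[j] = out[j - 1] + 1e-9
        return out

    meta = dict(animal_id=animal, timepoint=scenario.timepoint, pass_id=pass_id,
                task=scenario.task, surface=scenario.surface)
    contacts = {Limb.RH: rh_contacts, Limb.LH: _monotone(lh)}
    if scenario.forelimbs:
        contacts[Limb.RF] = _monotone(rf)
        contacts[Limb.LF] = _monotone(lf)
    events: dict[Limb, LimbEventSeries] = {}
    all_lifts = {}
    for limb, c in contacts.items():
        lifts = _lifts_from_contacts(c, duty, t_nominal)
        all_lifts[limb] = lifts
        events[limb] = LimbEventSeries(limb=limb, contacts=c, lifts=lifts, **meta)

    t_end = max(float(l[-1]) for l in all_lifts.values()) + 0.1
    grid = np.arange(0.0, t_end, 1.0 / scenario.frame_rate)
    body_x = v * grid
    markers: dict[str, MarkerTrack] = {
        "groin": MarkerTrack(Marker.GROIN, scenario.frame_rate,
                             np.column_stack([body_x, np.full_like(body_x, 3.0)]))
    }
    for limb, c in contacts.items():
        markers[f"paw_{limb.value.lower()}"] = _paw_track(
            c, all_lifts[limb], v * c, grid, scenario.frame_rate,
            y=1.0 if limb.is_hind else 2.0)
    return events, markers


def simulate_scenario(scenario: GaitScenario
                      ) -> tuple[list[LimbEventSeries],
                                 dict[tuple[str, str], dict[str, MarkerTrack]]]:
    """All passes of a scenario: flat event-series list plus per-pass markers."""
    events: list[LimbEventSeries] = []
    markers: dict[tuple[str, str], dict[str, MarkerTrack]] = {}
    for a in range(scenario.n_animals):
        for p in range(scenario.passes_per_animal):
            ev, mk = simulate_pass(scenario, a, p)
            events.extend(ev.values())
            markers[(f"A{a + 1}", f"{scenario.timepoint}-P{p + 1}")] = mk
    return events, markers


def simulate_angle_traces(windows, frame_rate: float = 200.0, *,
                          proximal_mean: float = 110.0, proximal_amp: float = 20.0,
                          distal_mean: float = 95.0, distal_amp: float = 35.0,
                          peak_phase: float = 0.6, lag: float = 0.05,
                          noise_deg: float = 0.0,
                          rng: np.random.Generator | None = None) -> list[AngleTrace]:
    """Smooth periodic proximal/distal angle traces over stride windows.

    Each trace is ``mean + amp·cos(2π(t/T − peak))`` with the proximal peak
    at ``peak_phase`` of the stride (end of stance by default, just prior to
    lift-off) and the distal peak lagging it by ``lag`` of a stride.
    Amplitudes are half the peak-to-trough excursion. ``windows`` is a
    sequence of (t_start, t_stop) stride intervals.
    """
    if proximal_amp <= 0 or distal_amp <= 0:
        raise ConfigError("angle amplitudes must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    traces = []
    for i, (t0, t1) in enumerate(windows):
        t = np.arange(t0, t1 + 0.5 / frame_rate, 1.0 / frame_rate)
        frac = (t - t0) / (t1 - t0)
        prox = proximal_mean + proximal_amp * np.cos(2 * np.pi * (frac - peak_phase))
        dist = distal_mean + distal_amp * np.cos(2 * np.pi * (frac - peak_phase - lag))
        if noise_deg > 0:
            prox = prox + rng.normal(0.0, noise_deg, size=t.size)
            dist = dist + rng.normal(0.0, noise_deg, size=t.size)
        traces.append(AngleTrace(f"S{i + 1}", t, prox, dist))
    return traces


def scenario_presets(seed: int = 0) -> dict[str, GaitScenario]:
    """Named scenarios mirroring the recording conditions the analyses target.

    ``control_overground``: tight alternation, no disrupted steps.
    ``lapn_silenced``: intact stride-speed laws but 25% of strides with
    left-limb phases redrawn uniformly (the silencing phenotype).
    ``treadmill``: silenced animals on a treadmill — narrower speed range,
    attenuated disruption. ``exploratory``: near-zero disruption.
    ``swim``: hindlimb-only alternation (forelimbs produce no events).
    """
    base = GaitScenario(name="control_overground", timepoint="BL", seed=seed)
    presets = {
        "control_overground": base,
        "lapn_silenced": replace(base, name="lapn_silenced", timepoint="DoxOn",
                                 disruption_rate=0.25),
        "treadmill": replace(base, name="treadmill", timepoint="DoxOn",
                             task="treadmill", speed_range=(20.0, 45.0),
                             disruption_rate=0.10),
        "exploratory": replace(base, name="exploratory", timepoint="DoxOn",
                               task="exploratory", speed_range=(20.0, 50.0),
                               disruption_rate=0.01),
        "swim": replace(base, name="swim", timepoint="BL", task="swim",
                        forelimbs=False, speed_range=(30.0, 60.0)),
    }
    return presets


def get_preset(name: str, seed: int = 0) -> GaitScenario:
    presets = scenario_presets(seed)
    if name not in presets:
        raise ConfigError(f"unknown preset {name!r}; one of {sorted(presets)}")
    return presets[name]
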