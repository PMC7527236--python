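"""End-to-end analysis pipeline: events → cycles → phases → bands →
classification → statistics → reports.

The pipeline reads long-format event (and optional marker) tables, extracts
complete step cycles per limb, computes the four limb-pair coupling phases
with the right limb of each pair as reference, pools control time points
into per-pair control-variability bands, flags altered steps, and emits the
figure-ready tables: per-step phases, proportion comparisons (control vs
silenced), Watson U² tests on the left-right couplings, gait labels,
phase-frequency counts and speed relations. Re-running with identical
inputs, configuration and seed reproduces identical outputs.

A counts-only entry point (:func:`compare_counts`) accepts pre-tabulated
altered/total counts so published comparisons can be reproduced without raw
per-step data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import circstat, gaits, interlimb, io, proptest
from .errors import ConfigError, QuadgaitError
from .gaits import GaitBands
from .interlimb import PAIR_LIMBS, LimbPair
from .io import Limb

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "compare_counts"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    events_path: str | Path
    out_dir: str | Path
    markers_path: str | Path | None = None
    frame_rate: float = 200.0
    control_timepoints: tuple[str, ...] = ("BL",)
    dox_timepoints: tuple[str, ...] = ("DoxOn",)
    band_k: float = 2.0
    frequency_threshold_hz: float = 5.0
    gait_bands: GaitBands = field(default_factory=GaitBands)
    min_cycles_per_pass: int = 3
    n_permutations: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band_k <= 0:
            raise ConfigError("band multiplier k must be positive")
        overlap = set(self.control_timepoints) & set(self.dox_timepoints)
        if overlap:
            raise ConfigError(f"control and dox timepoint labels overlap: {sorted(overlap)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "gait_bands" in raw:
            raw["gait_bands"] = GaitBands(**raw["gait_bands"])
        for key in ("control_timepoints", "dox_timepoints"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    phases: pd.DataFrame
    comparisons: pd.DataFrame
    gait_table: pd.DataFrame
    phase_frequency: pd.DataFrame
    u2_results: dict
    bands: dict
    stepping: pd.DataFrame
    cov: pd.DataFrame
    speed_relations: pd.DataFrame
    out_dir: Path


def _condition(timepoint: str, cfg: RunConfig) -> str | None:
    if timepoint in cfg.control_timepoints:
        return "control"
    if timepoint in cfg.dox_timepoints:
        return "dox"
    return None


def _extract_all(series_list, markers, cfg):
    """Per-(animal, timepoint, pass): limb -> (series, cycles)."""
    passes: dict[tuple[str, str, str], dict[Limb, tuple]] = {}
    for s in sorted(series_list, key=lambda s: (s.animal_id, s.timepoint, s.pass_id,
                                                s.limb.value)):
        key = (s.animal_id, s.timepoint, s.pass_id)
        mk = markers.get((s.animal_id, s.pass_id), {}) if markers else {}
        body = mk.get("groin")
        paw = mk.get(f"paw_{s.limb.value.lower()}")
        cycles = io.extract_step_cycles(s, body_track=body, paw_track=paw)
        passes.setdefault(key, {})[s.limb] = (s, cycles)
    # inclusion: the reference hindlimb must contribute enough complete cycles
    kept = {}
    for key, limbs in passes.items():
        rh = limbs.get(Limb.RH)
        if rh is None or len(rh[1]) < cfg.min_cycles_per_pass:
            logger.info("pass %s excluded (<%d complete reference cycles)",
                        key, cfg.min_cycles_per_pass)
            continue
        kept[key] = limbs
    return kept


def _collect_phases(passes, cfg):
    samples: dict[LimbPair, list[interlimb.PhaseSample]] = {p: [] for p in PAIR_LIMBS}
    for (animal, timepoint, pass_id), limbs in passes.items():
        for pair, (ref_limb, paired_limb) in PAIR_LIMBS.items():
            if ref_limb not in limbs or paired_limb not in limbs:
                continue
            ref_cycles = limbs[ref_limb][1]
            paired_series = limbs[paired_limb][0]
            samples[pair].extend(
                interlimb.compute_pair_phases(ref_cycles, paired_series, pair,
                                              animal_id=animal, timepoint=timepoint,
                                              pass_id=pass_id))
    return samples


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full coordination analysis and write the report bundle.

    Emits ``phases.csv``, ``comparisons.csv``, ``gaits.csv``, ``polar.csv``,
    ``u2_results.json``, ``band.yaml`` and ``summary.md`` under
    ``config.out_dir``. Any stage failure removes partial outputs and
    re-raises with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "read"
    try:
        series_list = io.read_event_table(config.events_path)
        if not series_list:
            raise QuadgaitError("event table contains no series")
        markers = (io.read_marker_table(config.markers_path, config.frame_rate)
                   if config.markers_path else {})

        stage = "cycles"
        passes = _extract_all(series_list, markers, config)
        if not passes:
            raise QuadgaitError("no pass met the minimum-cycle inclusion criterion")

        stage = "phases"
        samples = _collect_phases(passes, config)

        stage = "bands"
        bands = {}
        for pair, pair_samples in samples.items():
            control = [s for s in pair_samples
                       if _condition(s.timepoint, config) == "control"]
            if len(control) >= 2:
                bands[pair] = interlimb.build_control_band(control, pair,
                                                           k=config.band_k)

        stage = "classify"
        counts_rows = []
        for pair, band in bands.items():
            interlimb.classify_steps(samples[pair], band)
            for cond in ("control", "dox"):
                sub = [s for s in samples[pair]
                       if _condition(s.timepoint, config) == cond]
                counts_rows.append({"pair": pair.value, "condition": cond,
                                    "n_altered": sum(bool(s.altered) for s in sub),
                                    "n_total": len(sub)})
        counts = pd.DataFrame(counts_rows)

        stage = "proportions"
        contrasts = []
        for pair in bands:
            row = {c["condition"]: c for c in counts_rows if c["pair"] == pair.value}
            if row["control"]["n_total"] and row["dox"]["n_total"]:
                contrasts.append({"pair": pair.value, "contrast": "control_vs_dox",
                                  "x1": row["control"]["n_altered"],
                                  "n1": row["control"]["n_total"],
                                  "x2": row["dox"]["n_altered"],
                                  "n2": row["dox"]["n_total"]})
            else:
                logger.info("pair %s: missing contrast side, row skipped", pair.value)
        comparisons = proptest.proportion_report(contrasts)

        stage = "watson_u2"
        u2_results = {}
        for pair in (LimbPair.LR_FORE, LimbPair.LR_HIND):
            if pair not in samples:
                continue
            con = [s.raw_phase for s in samples[pair]
                   if _condition(s.timepoint, config) == "control"]
            dox = [s.raw_phase for s in samples[pair]
                   if _condition(s.timepoint, config) == "dox"]
            if len(con) >= 4 and len(dox) >= 4:
                res = circstat.watson_u2(con, dox, n_permutations=config.n_permutations,
                                         seed=config.seed)
                u2_results[pair.value] = {"pair": pair.value, **res.to_dict()}

        stage = "gaits"
        gait_rows = []
        for (animal, timepoint, pass_id), limbs in sorted(passes.items()):
            hind = [s for s in samples.get(LimbPair.LR_HIND, [])
                    if (s.animal_id, s.timepoint, s.pass_id) == (animal, timepoint, pass_id)]
            fore = [s for s in samples.get(LimbPair.LR_FORE, [])
                    if (s.animal_id, s.timepoint, s.pass_id) == (animal, timepoint, pass_id)]
            rh_cycles = limbs[Limb.RH][1]
            rf_cycles = limbs[Limb.RF][1] if Limb.RF in limbs else []
            hind_by_start = {round(c.start_contact, 9): s
                             for c, s in zip(rh_cycles, hind)} if len(hind) == len(rh_cycles) else {}
            for idx, cyc in enumerate(rh_cycles):
                hs = hind_by_start.get(round(cyc.start_contact, 9))
                # forelimb stride temporally overlapping this hind stride
                fs = None
                for fc, fsample in zip(rf_cycles, fore):
                    if cyc.start_contact <= fc.start_contact < cyc.end_contact:
                        fs = fsample
                        break
                if hs is None or fs is None:
                    label = gaits.GaitLabel.UNCLASSIFIED
                    hf, ff = np.nan, np.nan
                else:
                    hf, ff = hs.folded_phase, fs.folded_phase
                    label = gaits.classify_gait(hf, ff, config.gait_bands)
                gait_rows.append({"animal": animal, "timepoint": timepoint,
                                  "pass": pass_id, "stride": idx,
                                  "lr_hind_folded": hf, "lr_fore_folded": ff,
                                  "frequency_hz": cyc.frequency,
                                  "speed_cm_s": cyc.speed,
                                  "gait_label": label.value})
        gait_table = pd.DataFrame(gait_rows)

        stage = "phase_frequency"
        all_lr = samples.get(LimbPair.LR_FORE, []) + samples.get(LimbPair.LR_HIND, [])
        pf_counts, polar = gaits.phase_frequency_table(all_lr,
                                                       config.frequency_threshold_hz)

        stage = "stepping_index"
        step_rows = []
        for cond in ("control", "dox"):
            per_animal: dict[str, list[int]] = {}
            for (animal, timepoint, pass_id), limbs in sorted(passes.items()):
                if _condition(timepoint, config) != cond:
                    continue
                fore_n = sum(len(limbs[l][1]) for l in (Limb.LF, Limb.RF) if l in limbs)
                hind_n = sum(len(limbs[l][1]) for l in (Limb.LH, Limb.RH) if l in limbs)
                per_animal.setdefault(animal, [0, 0])
                per_animal[animal][0] += fore_n
                per_animal[animal][1] += hind_n
            for animal, (fore_n, hind_n) in sorted(per_animal.items()):
                if fore_n and hind_n:
                    step_rows.append({"animal": animal, "condition": cond,
                                      "stepping_index":
                                          interlimb.stepping_index(fore_n, hind_n)})
        stepping = pd.DataFrame(step_rows)

        stage = "cov"
        cov_rows = []
        for pair, pair_samples in samples.items():
            for (animal, timepoint), cov in sorted(
                    interlimb.coefficient_of_variation_by_group(pair_samples).items()):
                cond = _condition(timepoint, config)
                cov_rows.append({"pair": pair.value, "animal": animal,
                                 "timepoint": timepoint, "condition": cond,
                                 "cov_pct": cov})
        cov = pd.DataFrame(cov_rows)

        stage = "speed_relations"
        sr_rows = []
        rel_by_key = {}
        for cond in ("control", "dox"):
            hind_cycles = [c for (a, tp, p), limbs in passes.items()
                           if _condition(tp, config) == cond
                           for l in (Limb.LH, Limb.RH) if l in limbs
                           for c in limbs[l][1]]
            for var in gaits.SPEED_VARIABLES:
                try:
                    rel = gaits.speed_relation(hind_cycles, var)
                except QuadgaitError:
                    continue
                rel_by_key[(cond, var)] = rel
                sr_rows.append({"condition": cond, "variable": var,
                                "spearman_rs": rel.spearman_rs,
                                "r_squared": rel.r_squared, "slope": rel.slope,
                                "intercept": rel.intercept, "n": rel.n})
        speed_relations = pd.DataFrame(sr_rows)

        stage = "write"
        phases_df = pd.DataFrame(
            [{"animal": s.animal_id, "timepoint": s.timepoint,
              "condition": _condition(s.timepoint, config), "pair": s.pair.value,
              "pass": s.pass_id, "raw_phase": s.raw_phase,
              "folded_phase": s.folded_phase, "frequency_hz": s.frequency,
              "speed_cm_s": s.speed, "altered": s.altered}
             for pair in sorted(samples, key=lambda p: p.value)
             for s in samples[pair]])
        band_dump = {pair.value: {"mean": b.mean_folded, "sd": b.sd_folded,
                                  "lower": b.lower, "upper": b.upper,
                                  "k": b.k, "n": b.n}
                     for pair, b in sorted(bands.items(), key=lambda kv: kv[0].value)}

        def _write(name: str, writer) -> Path:
            p = out_dir / name
            writer(p)
            written.append(p)
            return p

        _write("phases.csv", lambda p: phases_df.to_csv(p, index=False))
        _write("comparisons.csv", lambda p: comparisons.to_csv(p, index=False))
        _write("gaits.csv", lambda p: gait_table.to_csv(p, index=False))
        _write("polar.csv", lambda p: polar.to_csv(p, index=False))
        _write("counts.csv", lambda p: counts.to_csv(p, index=False))
        _write("u2_results.json", lambda p: p.write_text(
            json.dumps(u2_results, indent=2, sort_keys=True) + "\n"))
        _write("band.yaml", lambda p: p.write_text(
            yaml.safe_dump(band_dump, sort_keys=True)))
        _write("summary.md", lambda p: p.write_text(
            _summary_md(config, counts, comparisons, stepping, gait_table,
                        pf_counts, u2_results)))
        logger.info("pipeline complete: %d passes, %d phase samples",
                    len(passes), sum(len(v) for v in samples.values()))
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise QuadgaitError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(phases=phases_df, comparisons=comparisons,
                          gait_table=gait_table, phase_frequency=pf_counts,
                          u2_results=u2_results, bands=bands, stepping=stepping,
                          cov=cov, speed_relations=speed_relations, out_dir=out_dir)


def _summary_md(config, counts, comparisons, stepping, gait_table, pf_counts,
                u2_results) -> str:
    lines = ["# Interlimb coordination summary", ""]
    lines.append(f"Band multiplier k = {config.band_k}; "
                 f"frequency threshold = {config.frequency_threshold_hz} Hz; "
                 f"seed = {config.seed}")
    lines.append("")
    lines.append("## Altered-step counts")
    for _, r in counts.iterrows():
        pct = 100.0 * r.n_altered / r.n_total if r.n_total else float("nan")
        lines.append(f"- {r['pair']} [{r.condition}]: {r.n_altered}/{r.n_total} "
                     f"({pct:.2f}%)")
    lines.append("")
    lines.append("## Proportion comparisons (unpooled two-sample z)")
    for _, r in comparisons.iterrows():
        lines.append(f"- {r['pair']} {r.contrast}: {r.pct1:.2f}% vs {r.pct2:.2f}%, "
                     f"|z| = {r.z:.2f}, p = {r.p:.3g}")
    lines.append("")
    if not stepping.empty:
        lines.append("## Quadrupedal stepping index (100 = 1:1)")
        for cond, grp in stepping.groupby("condition"):
            lines.append(f"- {cond}: {grp.stepping_index.mean():.2f} "
                         f"± {grp.stepping_index.std(ddof=1):.2f} (n = {len(grp)} animals)")
        lines.append("")
    if not gait_table.empty:
        lines.append("## Gait distribution")
        frac = gait_table.gait_label.value_counts(normalize=True)
        for label, f in frac.items():
            lines.append(f"- {label}: {100 * f:.1f}%")
        lines.append("")
    if u2_results:
        lines.append("## Watson U² (control vs dox, raw phases)")
        for pair, r in sorted(u2_results.items()):
            lines.append(f"- {pair}: U² = {r['u2']:.3f}, n1 = {r['n1']}, "
                         f"n2 = {r['n2']}, p = {r['p']:.3g}")
        lines.append("")
    return "\n".join(lines)


def compare_counts(entries: Iterable[Mapping], out_path: str | Path | None = None
                   ) -> pd.DataFrame:
    """Counts-only mode: proportion comparisons from pre-tabulated counts.

    ``entries`` may come from a YAML list of mappings with keys pair,
    contrast, x1, n1, x2, n2. Writes ``comparisons.csv`` when ``out_path``
    is given.
    """
    table = proptest.proportion_report(entries)
    if out_path is not None:
        table.to_csv(out_path, index=False)
    return table
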