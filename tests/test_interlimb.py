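import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadgait import (InsufficientDataError, QuadgaitError,
                      UndefinedStatisticError, build_control_band,
                      classify_steps, coefficient_of_variation, compute_phase,
                      extract_step_cycles, fold_phase, stepping_index)
from quadgait.interlimb import LimbPair, PhaseSample
from quadgait.io import Limb
from quadgait.synth import GaitScenario, simulate_pass

from conftest import make_series


def _sample(folded, pair=LimbPair.LR_HIND, **kw):
    defaults = dict(pair=pair, reference_limb=Limb.RH, raw_phase=folded,
                    folded_phase=folded, frequency=3.0)
    defaults.update(kw)
    return PhaseSample(**defaults)


class TestFolding:
    @pytest.mark.parametrize("raw,expected", [
        (0.5, 0.5), (0.25, 0.75), (0.75, 0.75), (0.0, 1.0), (0.125, 0.875),
    ])
    def test_folding_examples(self, raw, expected):
        assert fold_phase(raw) == pytest.approx(expected)

    @given(st.floats(min_value=0.0, max_value=0.999999))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_fold_idempotent_and_mirror_symmetric(self, x):
        f = fold_phase(x)
        assert 0.5 <= f <= 1.0
        assert fold_phase(f) == pytest.approx(f, abs=1e-12)
        assert fold_phase((1.0 - x) % 1.0) == pytest.approx(f, abs=1e-12)


class TestComputePhase:
    def _ref_cycle(self):
        return extract_step_cycles(make_series([0.0, 0.5], [0.3]))[0]

    @pytest.mark.parametrize("paired_contact,raw,folded", [
        (0.25, 0.5, 0.5),     # perfect alternation
        (0.125, 0.25, 0.75),  # gallop configuration, trailing
        (0.375, 0.75, 0.75),  # gallop configuration, leading — coincides folded
        (0.0, 0.0, 1.0),      # synchrony
    ])
    def test_phase_examples(self, paired_contact, raw, folded):
        paired = make_series([paired_contact, paired_contact + 0.5],
                             [paired_contact + 0.3], limb="LH")
        s = compute_phase(self._ref_cycle(), paired, LimbPair.LR_HIND)
        assert s.raw_phase == pytest.approx(raw)
        assert s.folded_phase == pytest.approx(folded)
        assert s.frequency == pytest.approx(2.0)

    def test_no_paired_contact_skipped(self):
        paired = make_series([0.6, 1.1], [0.9], limb="LH")
        assert compute_phase(self._ref_cycle(), paired, LimbPair.LR_HIND) is None

    def test_phase_invariant_under_time_translation(self):
        for dt in (0.0, 0.7, 5.0):
            ref = extract_step_cycles(make_series([0.0 + dt, 0.5 + dt], [0.3 + dt]))[0]
            paired = make_series([0.2 + dt, 0.7 + dt], [0.5 + dt], limb="LH")
            s = compute_phase(ref, paired, LimbPair.LR_HIND)
            assert s.raw_phase == pytest.approx(0.4)


class TestControlBand:
    def test_zero_variance_band(self):
        band = build_control_band([_sample(0.5)] * 3, LimbPair.LR_HIND)
        assert band.lower == band.upper == 0.5
        _, n_alt, _ = classify_steps([_sample(0.51)], band)
        assert n_alt == 1

    def test_hand_computed_band(self):
        band = build_control_band([_sample(v) for v in (0.50, 0.55, 0.60)],
                                  LimbPair.LR_HIND)
        assert band.mean_folded == pytest.approx(0.55)
        assert band.sd_folded == pytest.approx(0.05)
        assert band.lower == pytest.approx(0.5)   # clipped from 0.45
        assert band.upper == pytest.approx(0.65)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            build_control_band([_sample(0.5)], LimbPair.LR_HIND)

    def test_fresh_draw_coverage_of_k2_band(self):
        # tight von Mises around alternation: the folded distribution is
        # half-normal-like, so a mean + 2 SD band covers roughly 95-98%
        rng = np.random.default_rng(42)
        draw = (rng.vonmises(np.pi, 50.0, size=4000) / (2 * np.pi)) % 1.0
        folded = np.asarray(fold_phase(draw))
        band = build_control_band([_sample(v) for v in folded[:2000]],
                                  LimbPair.LR_HIND)
        fresh = folded[2000:]
        coverage = np.mean(band.contains(fresh))
        assert 0.93 <= coverage <= 0.99

    def test_band_mean_consistency_at_n500(self):
        # interior mean (0.75): folding is the identity there, so the band
        # mean must converge to the von Mises mean
        rng = np.random.default_rng(7)
        draw = (rng.vonmises(2 * np.pi * 0.75, 50.0, size=500) / (2 * np.pi)) % 1.0
        band = build_control_band([_sample(float(fold_phase(v))) for v in draw],
                                  LimbPair.LR_HIND)
        assert abs(band.mean_folded - 0.75) < 0.01


class TestClassifySteps:
    def test_partition(self):
        rng = np.random.default_rng(3)
        samples = [_sample(v) for v in rng.uniform(0.5, 1.0, size=200)]
        band = build_control_band(samples[:100], LimbPair.LR_HIND)
        annotated, n_alt, n_tot = classify_steps(samples, band)
        n_inside = sum(not s.altered for s in annotated)
        assert n_alt + n_inside == n_tot == len(samples)

    def test_all_at_band_mean_not_altered(self):
        band = build_control_band([_sample(v) for v in (0.5, 0.55, 0.6)],
                                  LimbPair.LR_HIND)
        _, n_alt, _ = classify_steps([_sample(band.mean_folded)] * 5, band)
        assert n_alt == 0

    def test_pair_mismatch_rejected(self):
        band = build_control_band([_sample(0.5), _sample(0.6)], LimbPair.LR_HIND)
        with pytest.raises(QuadgaitError):
            classify_steps([_sample(0.5, pair=LimbPair.LR_FORE)], band)

    def test_altered_count_monotone_in_k(self):
        rng = np.random.default_rng(5)
        samples = [_sample(v) for v in rng.uniform(0.5, 1.0, size=300)]
        counts = []
        for k in (0.5, 1.0, 2.0, 4.0, 50.0):
            band = build_control_band(samples, LimbPair.LR_HIND, k=k)
            counts.append(classify_steps(samples, band)[1])
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0

    def test_injected_uniform_steps_detected(self):
        # 25% decoupled (uniform folded) steps against a tight band: the
        # altered fraction matches the mixture expectation within binomial CI
        rng = np.random.default_rng(9)
        n = 2000
        control = 0.5 + np.abs(rng.vonmises(0, 200.0, size=n)) / (2 * np.pi)
        band = build_control_band([_sample(float(v)) for v in control[:1000]],
                                  LimbPair.LR_HIND)
        disrupted = rng.random(n // 1) < 0.25
        mixture = np.where(disrupted, rng.uniform(0.5, 1.0, size=n), control)
        _, n_alt, n_tot = classify_steps([_sample(float(v)) for v in mixture], band)
        p_in_uniform = (band.upper - band.lower) * 2.0  # uniform density on [0.5, 1]
        fpr = 1.0 - np.mean(band.contains(control[1000:]))
        expected = 0.25 * (1 - p_in_uniform) + 0.75 * fpr
        half = 1.96 * np.sqrt(expected * (1 - expected) / n)
        assert abs(n_alt / n_tot - expected) < half + 0.01


class TestCov:
    def test_constant_values_zero_cov(self):
        assert coefficient_of_variation([0.5, 0.5, 0.5]) == 0.0

    def test_hand_computed_cov(self):
        assert coefficient_of_variation([0.5, 0.6, 0.7]) == pytest.approx(
            100 * 0.1 / 0.6, abs=1e-9)

    def test_scale_invariance(self):
        x = np.array([0.5, 0.62, 0.71, 0.55])
        assert coefficient_of_variation(3.7 * x) == pytest.approx(
            coefficient_of_variation(x), abs=1e-9)


class TestSteppingIndex:
    @pytest.mark.parametrize("fore,hind,expected", [(10, 10, 100.0), (10, 11, 110.0)])
    def test_examples(self, fore, hind, expected):
        assert stepping_index(fore, hind) == pytest.approx(expected)

    def test_zero_forelimb_count_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            stepping_index(0, 10)

    def test_synthetic_coupled_bout_is_exactly_100(self):
        events, _ = simulate_pass(GaitScenario(seed=2), 0, 0)
        fore = sum(len(extract_step_cycles(events[l])) for l in (Limb.LF, Limb.RF))
        hind = sum(len(extract_step_cycles(events[l])) for l in (Limb.LH, Limb.RH))
        assert stepping_index(fore, hind) == 100.0
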