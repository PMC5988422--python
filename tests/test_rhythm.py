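"""Rhythm-metric tests: interpolation, the consensus rhythmicity filter,
amplitude rules, period variability, overlap de-duplication and phase stats."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phytosync.rhythm import (
    PeriodEstimator,
    RhythmResult,
    amplitude_stats,
    assess_rhythmicity,
    cosine_nlls_estimator,
    dedupe_overlaps,
    interpolate_trace,
    lomb_scargle_estimator,
    period_variability,
    section_phase_stats,
    _linear_detrend,
)
from phytosync.traces import CellTrace


def make_trace(times, values, cell_id="c0", section="root_tip", pos=(0.0, 0.0, 0.0)):
    return CellTrace(cell_id, pos, section, np.asarray(times, float), np.asarray(values, float))


class TestInterpolation:
    def test_identity_on_grid_aligned_input(self):
        t = np.arange(0.0, 10.0, 1.0)
        tr = interpolate_trace(make_trace(t, t**2), spacing=1.0)
        np.testing.assert_allclose(tr.values, t**2)

    def test_linear_midpoint(self):
        tr = interpolate_trace(make_trace([0.0, 2.0], [0.0, 4.0]), spacing=1.0)
        assert tr.values[1] == pytest.approx(2.0)

    def test_union_grid_matches_pointwise_linear_oracle(self, rng):
        # two sections sampled at offset times, interpolated to a shared grid
        t1 = np.arange(0.0, 30.0, 1.1)
        t2 = np.arange(0.4, 30.0, 3.0)
        v1, v2 = rng.normal(size=t1.size), rng.normal(size=t2.size)
        a = interpolate_trace(make_trace(t1, v1), spacing=1.0)
        b = interpolate_trace(make_trace(t2, v2), spacing=1.0)
        shared = np.intersect1d(a.times, b.times)
        for t in shared[:10]:
            # independent per-point oracle: manual two-point interpolation
            i = np.searchsorted(t1, t) - 1
            w = (t - t1[i]) / (t1[i + 1] - t1[i])
            assert a.values[a.times == t][0] == pytest.approx(
                (1 - w) * v1[i] + w * v1[i + 1]
            )

    def test_interpolated_values_bounded_by_neighbours(self, rng):
        t = np.sort(rng.uniform(0, 50, 40))
        t = t[np.r_[True, np.diff(t) > 1e-3]]
        v = rng.normal(size=t.size)
        tr = interpolate_trace(make_trace(t, v), spacing=0.7)
        assert tr.values.min() >= v.min() - 1e-12
        assert tr.values.max() <= v.max() + 1e-12

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            interpolate_trace(make_trace([1.0], [2.0]))


class TestRhythmicity:
    def test_pure_24h_cosine_is_rhythmic(self):
        t = np.arange(29.0, 168.0, 1.0)
        tr = make_trace(t, np.cos(2 * np.pi * t / 24.0))
        res = assess_rhythmicity(tr)
        assert res.rhythmic
        assert res.consensus_period == pytest.approx(24.0, abs=0.5)

    def test_constant_trace_not_rhythmic(self):
        t = np.arange(29.0, 168.0, 1.0)
        res = assess_rhythmicity(make_trace(t, np.full(t.size, 5.0)))
        assert not res.rhythmic
        assert math.isnan(res.consensus_period)

    def test_noise_trace_not_rhythmic(self, rng):
        t = np.arange(29.0, 168.0, 1.0)
        res = assess_rhythmicity(make_trace(t, rng.normal(size=t.size)))
        assert not res.rhythmic

    def test_estimator_disagreement_beyond_tolerance_vetoes(self):
        """Estimates 3 h apart exceed the 2.5 h consensus tolerance."""
        fake23 = PeriodEstimator("a", lambda t, v, w: (23.0, 0.0), gof_max=1.0)
        fake26 = PeriodEstimator("b", lambda t, v, w: (26.0, 0.0), gof_max=1.0)
        t = np.arange(29.0, 168.0, 1.0)
        tr = make_trace(t, np.cos(2 * np.pi * t / 24.0))
        res = assess_rhythmicity(tr, estimators=[fake23, fake26])
        assert not res.rhythmic
        res = assess_rhythmicity(
            tr,
            estimators=[
                fake23,
                PeriodEstimator("b", lambda t, v, w: (25.0, 0.0), gof_max=1.0),
            ],
        )
        assert res.rhythmic and res.consensus_period == 23.0

    def test_failing_gof_threshold_vetoes(self):
        good = PeriodEstimator("a", lambda t, v, w: (24.0, 0.0), gof_max=1.0)
        bad_gof = PeriodEstimator("b", lambda t, v, w: (24.0, 0.95), gof_max=0.9)
        t = np.arange(29.0, 168.0, 1.0)
        tr = make_trace(t, np.cos(2 * np.pi * t / 24.0))
        assert not assess_rhythmicity(tr, estimators=[good, bad_gof]).rhythmic

    def test_single_estimator_rejected(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(ValueError, match="2 estimators"):
            assess_rhythmicity(
                make_trace(t, np.cos(t)),
                estimators=[PeriodEstimator("a", lambda t, v, w: (24.0, 0.0), 1.0)],
            )

    @given(
        offset=st.floats(-100, 100),
        scale=st.floats(0.1, 50),
        tau=st.floats(20, 28),
    )
    def test_verdict_invariant_to_offset_and_positive_scaling(self, offset, scale, tau):
        t = np.arange(29.0, 150.0, 1.0)
        base = np.cos(2 * np.pi * t / tau)
        r1 = assess_rhythmicity(make_trace(t, base))
        r2 = assess_rhythmicity(make_trace(t, scale * base + offset))
        assert r1.rhythmic == r2.rhythmic
        assert r1.consensus_period == pytest.approx(r2.consensus_period, abs=0.05)

    @pytest.mark.parametrize("tau", [16.0, 19.3, 24.0, 27.8, 32.0])
    @pytest.mark.parametrize(
        "estimator", [cosine_nlls_estimator, lomb_scargle_estimator]
    )
    def test_estimator_contract_noiseless_sinusoid(self, tau, estimator):
        """Any configured estimator recovers tau within 0.5 h over >= 4 cycles."""
        t = np.arange(0.0, 4.3 * tau, 1.0)
        v = _linear_detrend(t, np.cos(2 * np.pi * t / tau + 1.0))
        period, _ = estimator(t, v)
        assert period == pytest.approx(tau, abs=0.5)


class TestAmplitude:
    def test_unit_cosine_amplitude_two(self):
        t = np.arange(0.0, 110.0, 1.0)  # > 4 cycles of 24 h
        tr = make_trace(t, np.cos(2 * np.pi * t / 24.0))
        res = assess_rhythmicity(tr)
        assert res.amplitude == pytest.approx(2.0, rel=0.02)
        assert len(res.peak_times) >= 4

    @given(amp=st.floats(0.5, 200), phase=st.floats(0, 2 * math.pi))
    def test_scaled_cosine_amplitude_2A(self, amp, phase):
        t = np.arange(0.0, 110.0, 1.0)
        tr = make_trace(t, amp * np.cos(2 * np.pi * t / 24.0 + phase))
        res = assess_rhythmicity(tr)
        assert res.amplitude == pytest.approx(2 * amp, rel=0.02)

    def test_two_peaks_gives_absent_amplitude(self):
        assert amplitude_stats([1.0, 25.0], [1.0, 1.0], [13.0], [-1.0]) is None

    def test_mismatched_peak_trough_counts_give_absent(self):
        assert (
            amplitude_stats([1, 25, 49], [1, 1, 1], [13], [-1]) is None
        )  # 3 peaks vs 1 trough

    def test_sawtooth_hand_enumerated_excursions(self):
        # alternating extrema with excursions 3,1,3,1,3 -> mean 2.2
        times = [0, 10, 20, 30, 40, 50]
        vals = [0.0, 3.0, 2.0, 5.0, 4.0, 7.0]
        amp = amplitude_stats(times[1::2], vals[1::2], times[0::2], vals[0::2])
        assert amp == pytest.approx(2.2)


class TestVariability:
    def _result(self, cid, peaks):
        return RhythmResult(
            cell_id=cid, section="s", position=(0, 0, 0),
            period_estimates={}, gof={}, rhythmic=True, consensus_period=24.0,
            peak_times=np.asarray(peaks, float),
        )

    def test_perfect_cosines_zero_variability(self):
        res = [self._result(f"c{i}", [0, 24, 48, 72]) for i in range(4)]
        v = period_variability(res)
        assert v.between_cell_sd == 0.0 and v.within_cell_sd == 0.0

    def test_two_cells_constant_intervals(self):
        res = [self._result("a", [0, 23, 46, 69]), self._result("b", [0, 25, 50, 75])]
        v = period_variability(res)
        assert v.within_cell_sd == pytest.approx(0.0)
        assert v.between_cell_sd == pytest.approx(math.sqrt(2))

    def test_generator_period_sd_recovered(self):
        """Between-cell SD tracks the drawn period spread (no phase diffusion)."""
        from phytosync.synthetic import GeneratorConfig, SectionProfile, \
            generate_layout, generate_traces

        sp = SectionProfile("s", 25, 24.0, 1.0, 40.0, 2.0, (0.0, 1.0))
        cfg = GeneratorConfig(sections=[sp], t_start=0, t_end=168,
                              sampling_interval=1.0, noise_sd=0.0,
                              amplitude_cv=0.0, rng_seed=13)
        traces = generate_traces(generate_layout(cfg), cfg)
        res = [assess_rhythmicity(t) for t in traces]
        v = period_variability(res)
        assert v.between_cell_sd == pytest.approx(1.0, abs=0.35)
        assert v.within_cell_sd < 0.5

    def test_fewer_than_two_cells_rejected(self):
        with pytest.raises(ValueError):
            period_variability([self._result("a", [0, 24, 48])])


class TestDedupe:
    def _cell(self, cid, section, x, y):
        return make_trace([0, 1], [0, 0], cell_id=cid, section=section, pos=(x, y, 0))

    def test_disjoint_sections_identity(self):
        cells = [self._cell("a", "s1", 0.5, 0.5), self._cell("b", "s2", 2.5, 2.5)]
        kept, removed = dedupe_overlaps(
            cells, {"s1": (0, 0, 1, 1), "s2": (2, 2, 3, 3)}
        )
        assert kept == cells and removed == {}

    def test_cell_in_overlap_assigned_to_higher_section_removed(self):
        boxes = {"lower_hypocotyl": (0, 0, 2, 2), "upper_hypocotyl": (0, 1.5, 2, 3.5)}
        cells = [
            self._cell("keep", "lower_hypocotyl", 1.0, 1.7),
            self._cell("drop", "upper_hypocotyl", 1.0, 1.7),
            self._cell("stay", "upper_hypocotyl", 1.0, 3.0),
        ]
        kept, removed = dedupe_overlaps(cells, boxes)
        assert [c.cell_id for c in kept] == ["keep", "stay"]
        assert removed == {"upper_hypocotyl": 1}

    def test_constructed_overlap_count(self, rng):
        k = 7
        boxes = {"A": (0, 0, 4, 4), "B": (0, 3, 4, 7)}
        cells = [self._cell(f"a{i}", "A", 2, rng.uniform(0, 3)) for i in range(10)]
        cells += [self._cell(f"b{i}", "B", 2, rng.uniform(3.1, 3.9)) for i in range(k)]
        cells += [self._cell(f"b_out{i}", "B", 2, rng.uniform(4.1, 6.9)) for i in range(5)]
        kept, removed = dedupe_overlaps(cells, boxes)
        assert len(kept) == len(cells) - k
        assert removed == {"B": k}


class TestPhaseStats:
    def _result(self, cid, section, peaks):
        return RhythmResult(
            cell_id=cid, section=section, position=(0, 0, 0),
            period_estimates={}, gof={}, rhythmic=True, consensus_period=24.0,
            peak_times=np.asarray(peaks, float),
        )

    def test_identical_peaks(self):
        res = [self._result(f"c{i}", "root_tip", [50.0]) for i in range(5)]
        s = section_phase_stats(res)["root_tip"]
        assert s["mean"] == 50.0 and s["sd"] == 0.0 and s["n"] == 5

    def test_simple_arithmetic(self):
        res = [
            self._result("a", "s", [49.0, 73.0]),
            self._result("b", "s", [51.0]),
            self._result("c", "s", [53.0]),
        ]
        s = section_phase_stats(res)["s"]
        assert s["mean"] == pytest.approx(51.0)
        assert s["sd"] == pytest.approx(2.0)

    def test_earliest_in_window_peak_used(self):
        res = [self._result("a", "s", [30.0, 50.0, 70.0])]
        assert section_phase_stats(res)["s"]["mean"] == 50.0

    def test_section_without_in_window_peaks_absent(self):
        res = [self._result("a", "s", [30.0])]
        assert "s" not in section_phase_stats(res)
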