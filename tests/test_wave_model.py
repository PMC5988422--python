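"""Spatial phase-oscillator model tests: template construction, Euler
dynamics, bioluminescence mapping and space-time plots."""

import numpy as np
import pytest
from scipy import stats
from scipy.signal import find_peaks

from phytosync.rhythm import RhythmResult
from phytosync.wave_model import (
    DEFAULT_PERIODS,
    SeedlingTemplate,
    bioluminescence,
    build_template,
    peak_time_table,
    simulate_field,
    spacetime_from_field,
)


def single_cell_template(section="shoot", period=None):
    periods = {section: DEFAULT_PERIODS.get(section, 24.0) if period is None else period}
    return SeedlingTemplate(np.ones((1, 1), bool), np.array([section]), periods)


class TestTemplate:
    def test_default_build_section_periods(self):
        tmpl = build_template()
        assert tmpl.periods["root_tip"] == 22.67
        assert tmpl.periods["root"] == 25.55
        assert tmpl.periods["shoot"] == 24.0
        assert tmpl.section_of_row[0] == "root_tip"
        assert tmpl.section_of_row[-1] == "shoot"

    def test_mask_symmetric_about_midline(self):
        m = build_template().mask
        np.testing.assert_array_equal(m, m[:, ::-1])

    def test_single_row_template_valid(self):
        t = single_cell_template()
        assert t.n_rows == 1 and t.width_of_row[0] == 1

    def test_asymmetric_mask_rejected(self):
        mask = np.zeros((2, 3), bool)
        mask[:, 0] = True
        with pytest.raises(ValueError, match="symmetric"):
            SeedlingTemplate(mask, np.array(["root", "root"]), {"root": 25.0})

    def test_unassigned_occupied_row_rejected(self):
        mask = np.ones((2, 1), bool)
        with pytest.raises(ValueError, match="section"):
            SeedlingTemplate(mask, np.array(["root", "mystery"]), {"root": 25.0})

    def test_bad_partition_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            build_template(n_rows=10, root_tip_rows=6, shoot_rows=6)


class TestDynamics:
    def test_uncoupled_cell_advances_at_intrinsic_frequency(self):
        tmpl = single_cell_template(period=24.0)
        f = simulate_field(tmpl, K=0.0, dt=0.05, t_end=48.0)
        theta = f.theta[:, 0, 0]
        np.testing.assert_allclose(theta, 2 * np.pi * f.times / 24.0, atol=1e-9)

    @pytest.mark.parametrize("section,period", list(DEFAULT_PERIODS.items()))
    def test_free_running_period_from_bioluminescence_peaks(self, section, period):
        tmpl = single_cell_template(section, period)
        f = simulate_field(tmpl, K=0.0, dt=0.05, t_end=200.0)
        B = bioluminescence(f)[:, 0, 0]
        pk, _ = find_peaks(B, distance=int(0.5 * period / 0.05))
        mean_interval = float(np.mean(np.diff(f.times[pk])))
        assert mean_interval == pytest.approx(period, abs=0.1)

    def test_two_identical_coupled_cells_stay_identical(self):
        mask = np.ones((2, 1), bool)
        tmpl = SeedlingTemplate(mask, np.array(["root", "root"]), {"root": 25.0})
        f = simulate_field(tmpl, K=1.0, dt=0.05, t_end=100.0)
        np.testing.assert_allclose(f.theta[:, 0, 0], f.theta[:, 1, 0], atol=1e-12)

    def test_phase_shift_equivariance(self):
        tmpl = build_template(n_rows=12, root_tip_rows=3, shoot_rows=3)
        init = np.random.default_rng(1).uniform(0, 2 * np.pi, tmpl.mask.shape)
        f0 = simulate_field(tmpl, K=1.0, dt=0.05, t_end=20.0, initial_phases=init)
        f1 = simulate_field(tmpl, K=1.0, dt=0.05, t_end=20.0, initial_phases=init + 0.7)
        d = (f1.theta - f0.theta)[:, tmpl.mask]
        np.testing.assert_allclose(d, 0.7, atol=1e-9)

    def test_identical_period_random_phases_synchronise(self):
        tmpl = build_template(
            n_rows=12, root_tip_rows=3, shoot_rows=3,
            periods={"shoot": 24.0, "root": 24.0, "root_tip": 24.0},
        )
        f = simulate_field(tmpl, K=1.0, dt=0.05, t_end=200.0, rng_seed=3, store_every=20)
        m = tmpl.mask
        R = np.abs(np.mean(np.exp(1j * f.theta[:, m]), axis=1))
        assert R[-1] > R[0]
        # order parameter climbs monotonically apart from numerical wiggle
        assert np.min(np.diff(R)) > -1e-3

    def test_empty_template_rejected(self):
        with pytest.raises(ValueError):
            SeedlingTemplate(np.zeros((2, 2), bool), np.array(["a", "b"]), {"a": 24})


class TestBioluminescence:
    def test_pointwise_values_and_bounds(self):
        tmpl = single_cell_template(period=24.0)
        f = simulate_field(tmpl, K=0.0, dt=0.05, t_end=48.0)
        B = bioluminescence(f)[:, 0, 0]
        assert B[0] == pytest.approx(2.0)  # theta = 0
        assert B.min() >= 0.0 and B.max() <= 2.0
        i_pi = int(round(12.0 / 0.05))  # theta = pi at half period
        assert B[i_pi] == pytest.approx(0.0, abs=1e-4)

    def test_cycle_average_is_one(self):
        tmpl = single_cell_template(period=24.0)
        f = simulate_field(tmpl, K=0.0, dt=0.05, t_end=24.0)
        B = bioluminescence(f)[:-1, 0, 0]  # one full cycle, endpoint excluded
        assert np.mean(B) == pytest.approx(1.0, abs=1e-6)


class TestSpaceTime:
    def test_rows_peak_normalised_to_one(self):
        f = simulate_field(build_template(), K=1.0, dt=0.05, t_end=100.0, store_every=10)
        stm = spacetime_from_field(f)
        np.testing.assert_allclose(stm.values.max(axis=1), 1.0, atol=1e-12)

    def test_uniform_phase_rows_identical(self):
        tmpl = build_template(
            n_rows=12, root_tip_rows=3, shoot_rows=3, root_width=4, shoot_width=4,
            periods={"shoot": 24.0, "root": 24.0, "root_tip": 24.0},
        )
        f = simulate_field(tmpl, K=0.0, dt=0.05, t_end=72.0, store_every=10)
        stm = spacetime_from_field(f)
        for row in stm.values[1:]:
            np.testing.assert_allclose(row, stm.values[0], atol=1e-12)

    def test_left_right_reflection_leaves_rows_unchanged(self):
        tmpl = build_template(n_rows=12, root_tip_rows=3, shoot_rows=3)
        init = np.random.default_rng(2).uniform(0, 2 * np.pi, tmpl.mask.shape)
        init = (init + init[:, ::-1]) / 2  # symmetric initial condition
        f = simulate_field(tmpl, K=1.0, dt=0.05, t_end=50.0, initial_phases=init)
        f_ref = simulate_field(
            tmpl, K=1.0, dt=0.05, t_end=50.0, initial_phases=init[:, ::-1]
        )
        a, b = spacetime_from_field(f), spacetime_from_field(f_ref)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_bow_wave_row_interior_to_root(self):
        """With shoot-synchronised release the latest first-cycle peak sits
        strictly between root tip and shoot: two waves meet mid-root."""
        tmpl = build_template()
        f = simulate_field(tmpl, K=1.0, dt=0.05, t_end=200.0, store_every=10)
        stm = spacetime_from_field(f)
        fp = stm.first_peak_time_by_row()
        latest = int(stm.rows[np.nanargmax(fp)])
        assert 6 <= latest < 60 - 14  # inside the root section


class TestPeakTimeTable:
    def _result(self, cid, section, y, peaks):
        return RhythmResult(
            cell_id=cid, section=section, position=(0.0, y, 0.0),
            period_estimates={}, gof={}, rhythmic=True, consensus_period=24.0,
            peak_times=np.asarray(peaks, float),
        )

    def test_identical_peaks_vertical_line(self):
        res = [self._result(f"c{i}", "s", 0.1 * i, [50.0]) for i in range(5)]
        table = peak_time_table(res)
        assert (table["peak_time_h"] == 50.0).all()

    def test_linear_gradient_recovered(self):
        slope_true = 2.5  # h per mm
        res = [
            self._result(f"c{i}", "s", y, [50.0 + slope_true * y])
            for i, y in enumerate(np.linspace(0, 4, 30))
        ]
        table = peak_time_table(res)
        fit = stats.linregress(table["y_mm"], table["peak_time_h"])
        assert fit.slope == pytest.approx(slope_true, rel=1e-9)

    def test_section_ordering_of_mean_phases(self):
        """Earlier clock in the hypocotyl than cotyledon than upper root."""
        from phytosync.rhythm import assess_rhythmicity, section_phase_stats
        from phytosync.synthetic import (
            GeneratorConfig,
            SectionProfile,
            generate_layout,
            generate_traces,
        )

        secs = [
            SectionProfile("upper_hypocotyl", 10, 24.0, 0.5, 51.2, 1.1, (5.0, 6.5)),
            SectionProfile("cotyledon", 10, 24.0, 0.5, 55.6, 2.3, (6.5, 8.0)),
            SectionProfile("upper_root", 10, 25.55, 0.5, 56.6, 4.5, (2.0, 3.5)),
        ]
        cfg = GeneratorConfig(sections=secs, rng_seed=9, noise_sd=1.0)
        res = [assess_rhythmicity(t) for t in generate_traces(generate_layout(cfg), cfg)]
        stats_ = section_phase_stats(res)
        assert (
            stats_["upper_hypocotyl"]["mean"]
            < stats_["cotyledon"]["mean"]
            <= stats_["upper_root"]["mean"] + 1.0
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            peak_time_table([])
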