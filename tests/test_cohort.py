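"""Synthetic-cohort generator contracts: study design, determinism,
trend consistency, artifact construction and truth-table round-trip."""

import io
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from threetau import reference
from threetau.cohort import (CohortSpec, generate_cohort, params_from_row,
                             read_truth, sample_parameters, simulate_profile,
                             write_truth)
from threetau.model import r1_total
from threetau.profiles import GROUPS, apply_exclusions
from threetau.reference import QuantityTrend, default_trends


def _zero_scatter_trends():
    return {name: replace(tr, scatter_sd=0.0, group_offsets=(0.0, 0.0, 0.0))
            for name, tr in default_trends().items()}


class TestTrendTable:
    def test_intercepts_follow_percent_change_arithmetic(self):
        trends = default_trends()
        tb = trends["tau_b_ps"]
        assert tb.gradient == -0.238
        assert tb.intercept == pytest.approx(-0.238 * 100 / -0.57, rel=1e-12)
        assert tb.intercept == pytest.approx(41.75, abs=0.01)
        td = trends["tau_d_us"]
        assert td.intercept == pytest.approx(0.139, abs=5e-4)
        assert 0.03 <= td.intercept <= 0.2  # printed surface-time range
        nl = trends["N_l"]
        assert nl.intercept == pytest.approx(20.79, abs=0.01)
        assert 20.0 <= nl.intercept <= 35.0  # printed healthy-tissue range

    def test_all_printed_gradients_present(self):
        trends = default_trends()
        assert trends["tau_l_us"].gradient == -2.515e-4
        assert trends["tau_d_us"].gradient == -3.347e-4
        assert trends["x"].gradient == -3.076e-5
        assert trends["N_l"].gradient == 2.079e-2
        assert trends["N_sigma"].gradient == -1.899e-3
        assert trends["R1_001MHz"].gradient == -0.121


class TestSampleParameters:
    def test_study_design_sizes_and_controls(self):
        spec = CohortSpec(seed=4)
        truth = sample_parameters(spec, np.random.default_rng(4))
        assert len(truth) == 32
        counts = truth["group"].value_counts()
        assert counts["4T1"] == 11 and counts["FARN"] == 11 and counts["TSA"] == 10
        c = truth["tumour_fraction_percent"]
        assert ((c >= 0) & (c <= 83)).all()
        assert (truth.groupby("group")["tumour_fraction_percent"].min() == 0).all()

    def test_zero_scatter_lies_on_trend_lines(self):
        spec = CohortSpec(seed=4, trends=_zero_scatter_trends())
        truth = sample_parameters(spec, np.random.default_rng(4))
        trends = spec.trends
        for q in ("tau_b_ps", "x", "N_l"):
            expected = trends[q].mean_at(truth["tumour_fraction_percent"])
            assert np.allclose(truth[q], expected, rtol=1e-12)

    def test_deterministic_under_seed(self):
        spec = CohortSpec(seed=9)
        a = sample_parameters(spec, np.random.default_rng(9))
        b = sample_parameters(spec, np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)

    def test_generator_gradient_recovered_from_truth(self):
        """OLS slope of true tau_b against c is statistically compatible
        with the generator gradient."""
        spec = CohortSpec(seed=17)
        truth = sample_parameters(spec, np.random.default_rng(17))
        c = truth["tumour_fraction_percent"].to_numpy()
        y = truth["tau_b_ps"].to_numpy()
        slope, intercept = np.polyfit(c, y, 1)
        resid = y - (slope * c + intercept)
        se = np.sqrt(np.sum(resid ** 2) / (len(c) - 2)
                     / np.sum((c - c.mean()) ** 2))
        assert abs(slope - spec.trends["tau_b_ps"].gradient) < 3 * se + 3 * \
            spec.trends["tau_b_ps"].scatter_sd / np.sqrt(np.sum((c - c.mean()) ** 2))


class TestSimulateProfile:
    def test_artifact_free_profile_equals_forward_model(self, healthy_params):
        spec = CohortSpec(seed=1, noise_rel_sd=0.0, quad_rel_amplitude=0.0,
                          switch_rel_offset=0.0)
        prof = simulate_profile(healthy_params, spec, np.random.default_rng(1))
        assert np.allclose(prof.r1, r1_total(prof.frequency_mhz, healthy_params),
                           rtol=1e-12)

    def test_quadrupolar_bump_magnitude(self, healthy_params):
        spec = CohortSpec(seed=1, noise_rel_sd=0.0, switch_rel_offset=0.0)
        prof = simulate_profile(healthy_params, spec, np.random.default_rng(1))
        clean = r1_total(prof.frequency_mhz, healthy_params)
        i2 = int(np.argmin(np.abs(np.log10(prof.frequency_mhz / 2.0))))
        boost = prof.r1[i2] / clean[i2] - 1.0
        assert boost == pytest.approx(0.05, abs=0.015)
        far = np.abs(np.log10(prof.frequency_mhz / 2.0)) > 0.3
        in_band = prof.frequency_mhz <= spec.switch_mhz
        assert np.allclose(prof.r1[far & in_band], clean[far & in_band],
                           rtol=1e-3)

    def test_switch_step_applies_beyond_cutoff(self, healthy_params):
        spec = CohortSpec(seed=1, noise_rel_sd=0.0, quad_rel_amplitude=0.0)
        prof = simulate_profile(healthy_params, spec, np.random.default_rng(1))
        clean = r1_total(prof.frequency_mhz, healthy_params)
        above = prof.frequency_mhz > 8.0
        assert np.allclose(prof.r1[above] / clean[above], 0.95, rtol=1e-12)
        assert np.allclose(prof.r1[~above], clean[~above], rtol=1e-12)

    def test_artifacts_fall_in_masked_regions(self, healthy_params):
        """After default exclusions a noiseless-but-artifacted profile
        refits its generating tau_b within 10%."""
        from threetau.fitting import FitConfig, fit_profile
        spec = CohortSpec(seed=1, noise_rel_sd=0.0)
        prof = simulate_profile(healthy_params, spec, np.random.default_rng(1))
        filtered = apply_exclusions(prof)
        res = fit_profile(filtered, FitConfig(seed=2))
        assert res.params.tau_b * 1e12 == pytest.approx(
            healthy_params.tau_b * 1e12, rel=0.10)


class TestGenerateCohort:
    def test_default_cohort_shape_and_determinism(self):
        spec = CohortSpec(seed=6)
        profiles, truth = generate_cohort(spec)
        assert len(profiles) == 32
        assert [p.sample_id for p in profiles] == truth["sample_id"].tolist()
        assert all(p.n_points == 28 for p in profiles)
        profiles2, truth2 = generate_cohort(spec)
        pd.testing.assert_frame_equal(truth, truth2)
        for a, b in zip(profiles, profiles2):
            assert np.array_equal(a.r1, b.r1)

    def test_truth_round_trip_at_nine_digits(self):
        spec = CohortSpec(seed=6)
        _, truth = generate_cohort(spec)
        buf = io.StringIO()
        write_truth(truth, buf)
        buf.seek(0)
        back = read_truth(buf)
        for col in ("tau_b_ps", "x", "N_l", "N_sigma"):
            assert np.allclose(back[col], truth[col], rtol=1e-8)

    def test_params_from_row_round_trip(self):
        spec = CohortSpec(seed=6)
        _, truth = generate_cohort(spec)
        p = params_from_row(truth.iloc[0])
        assert p.tau_b == pytest.approx(truth.iloc[0]["tau_b_ps"] * 1e-12)
        assert p.N_l == truth.iloc[0]["N_l"]
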