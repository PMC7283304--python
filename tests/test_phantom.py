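"""Phantom generator: AIF model, tissue curves, subjects and cohorts."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctperf.phantom import (
    AIFSpec,
    CohortSampler,
    InvalidSpecError,
    PhantomSpec,
    RegionSpec,
    build_cohort,
    build_subject,
    evaluate_aif,
    simulate_tissue_curve,
)


class TestEvaluateAif:
    def test_zero_before_bolus_arrival(self):
        spec = AIFSpec(t0=8.0)
        vals = evaluate_aif(spec, np.array([0.0, 2, 4, 6, 8]))
        assert np.all(vals == 0.0)

    def test_peak_at_alpha_beta(self):
        # d/dt of the gamma-variate vanishes at t0 + alpha*beta; confirm by
        # dense grid search.
        spec = AIFSpec(amplitude=1.0, t0=0.0, alpha=3.0, beta=1.5)
        dense = np.linspace(0, 30, 300001)
        vals = evaluate_aif(spec, dense)
        assert dense[np.argmax(vals)] == pytest.approx(4.5, abs=1e-3)

    def test_linear_in_amplitude(self, times):
        v1 = evaluate_aif(AIFSpec(amplitude=1.0), times)
        v2 = evaluate_aif(AIFSpec(amplitude=2.0), times)
        np.testing.assert_array_equal(v2, 2.0 * v1)

    @pytest.mark.parametrize("bad", [{"beta": -1.0}, {"beta": 0.0},
                                     {"amplitude": 0.0}, {"amplitude": -2.0}])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(InvalidSpecError):
            AIFSpec(**bad)

    @settings(derandomize=True, max_examples=50)
    @given(amp=st.floats(0.1, 100), t0=st.floats(0, 20),
           alpha=st.floats(0.5, 6), beta=st.floats(0.2, 5))
    def test_nonnegative_and_finite(self, amp, t0, alpha, beta):
        vals = evaluate_aif(AIFSpec(amp, t0, alpha, beta), np.arange(40) * 1.5)
        assert np.all(np.isfinite(vals)) and np.all(vals >= 0)


class TestSimulateTissueCurve:
    def test_zero_flow_gives_zero_curve(self, aif_curve):
        curve = simulate_tissue_curve(aif_curve, 0.0, 4.0, 0.0, 2.0)
        assert np.all(curve == 0.0)

    def test_delay_is_pure_sample_shift(self, aif_curve):
        c0 = simulate_tissue_curve(aif_curve, 60, 4, 0.0, 2.0)
        c4 = simulate_tissue_curve(aif_curve, 60, 4, 4.0, 2.0)
        np.testing.assert_array_equal(c4[2:], c0[:-2])
        assert np.all(c4[:2] == 0.0)

    @staticmethod
    def _boxcar_error(dt: float) -> float:
        """Max deviation of the discrete model from a dt=0.01 brute-force
        convolution oracle, for a boxcar AIF and exponential residue."""
        n = int(round(60.0 / dt))
        t = np.arange(n) * dt
        aif = ((t >= 4) & (t < 16)).astype(float) * 5.0
        coarse = simulate_tissue_curve(aif, 60.0, 4.0, 0.0, dt)

        dtf = 0.01
        tf = np.arange(0, 60.0, dtf)
        aif_f = ((tf >= 4) & (tf < 16)).astype(float) * 5.0
        resid_f = np.exp(-tf / 4.0)
        fine = (60.0 / 6000.0) * dtf * np.convolve(aif_f, resid_f)[: tf.size]
        fine_sampled = fine[:: int(round(dt / dtf))]
        return float(np.max(np.abs(coarse - fine_sampled)))

    def test_against_fine_grid_convolution(self):
        # The Riemann-sum model deviates from the continuous convolution by
        # at most one quadrature cell F*dt*max(aif) (the boxcar jump), and
        # the deviation shrinks with the step as expected of an O(dt) rule.
        flow_scale = 60.0 / 6000.0
        err_coarse = self._boxcar_error(2.0)
        err_fine = self._boxcar_error(0.5)
        assert err_coarse <= flow_scale * 2.0 * 5.0 + 1e-12
        assert err_fine <= flow_scale * 0.5 * 5.0 + 1e-12
        assert err_fine < err_coarse / 2.0

    def test_area_ratio_matches_central_volume(self, aif_curve):
        # On a long window the tissue/AIF area ratio approaches
        # CBF*MTT/6000 (within the discrete-model half-sample bias).
        dt = 2.0
        curve = simulate_tissue_curve(aif_curve, 30.0, 5.0, 0.0, dt)
        ratio = curve.sum() / aif_curve.sum()
        expected = 30.0 * 5.0 / 6000.0
        assert ratio == pytest.approx(expected, rel=0.3)

    def test_invalid_mtt_rejected(self, aif_curve):
        with pytest.raises(InvalidSpecError):
            simulate_tissue_curve(aif_curve, 60, 0.0, 0, 2.0)

    def test_nonnegative_and_peak_after_aif_peak(self, aif_curve):
        curve = simulate_tissue_curve(aif_curve, 60, 4, 6.0, 2.0)
        assert np.all(curve >= 0)
        assert 2.0 * np.argmax(curve) >= 2.0 * np.argmax(aif_curve) + 6.0 - 2.0


class TestBuildSubject:
    def test_uniform_phantom_all_curves_identical(self):
        regions = (RegionSpec("normal", cbf_true=40.0, mtt_true=5.0),)
        spec = PhantomSpec(regions=regions, noise_sd=0.0)
        study, _ = build_subject(spec, "A", seed=0)
        flat = study.data.reshape(-1, spec.n_timepoints)
        np.testing.assert_array_equal(flat, np.broadcast_to(flat[0], flat.shape))

    def test_group_a_fiv_is_core_union_penumbra(self, noiseless_spec):
        study_a, truth_a = build_subject(noiseless_spec, "A", seed=0)
        study_b, truth_b = build_subject(noiseless_spec, "B", seed=0)
        n_core = np.count_nonzero(truth_a.region_label_map == 2)
        n_pen = np.count_nonzero(truth_a.region_label_map == 1)
        assert truth_a.fiv_mask_true.sum() == n_core + n_pen
        assert truth_b.fiv_mask_true.sum() == n_core

    def test_seed_determinism(self):
        spec = PhantomSpec()
        s1, t1 = build_subject(spec, "A", seed=7)
        s2, t2 = build_subject(spec, "A", seed=7)
        np.testing.assert_array_equal(s1.data, s2.data)
        np.testing.assert_array_equal(t1.fiv_mask_true, t2.fiv_mask_true)

    def test_lesion_crossing_midline_rejected(self):
        regions = (
            RegionSpec("normal", cbf_true=60, mtt_true=4),
            RegionSpec("penumbra", cbf_true=25, mtt_true=7, delay_true=3,
                       center=(16.0, 16.0, 4.0), radii=(4.0, 4.0, 2.0)),
        )
        with pytest.raises(InvalidSpecError, match="midline"):
            PhantomSpec(regions=regions)

    def test_truth_obeys_central_volume_principle(self, noiseless_spec):
        _, truth = build_subject(noiseless_spec, "A", seed=0)
        np.testing.assert_allclose(
            truth.cbv_true, truth.cbf_true * truth.mtt_true / 60.0, atol=1e-12
        )

    def test_normal_hemisphere_truth_mirror_symmetric(self, noiseless_spec):
        _, truth = build_subject(noiseless_spec, "A", seed=0)
        outside = truth.region_label_map == 0
        mirrored = truth.cbf_true[::-1]
        both_normal = outside & outside[::-1]
        np.testing.assert_array_equal(truth.cbf_true[both_normal],
                                      mirrored[both_normal])

    def test_partial_coverage_is_central_slab(self):
        spec = PhantomSpec(noise_sd=0.0, coverage_fraction=0.5)
        study, _ = build_subject(spec, "A", seed=0)
        nz = spec.grid_shape[2]
        covered_z = np.unique(np.nonzero(study.coverage_mask)[2])
        assert covered_z.size == nz // 2


class TestBuildCohort:
    def test_one_subject_per_group(self):
        cohort = build_cohort(1, 1, seed=0)
        assert [c[0].group for c in cohort] == ["A", "B"]

    def test_default_cohort_size_is_54(self):
        cohort = build_cohort(seed=0)
        groups = [c[0].group for c in cohort]
        assert len(cohort) == 54
        assert groups.count("A") == 25 and groups.count("B") == 29

    def test_degenerate_ranges_pin_parameters(self):
        sampler = CohortSampler(
            normal_cbf=(60.0, 60.0), normal_mtt=(4.0, 4.0),
            penumbra_cbf=(25.0, 25.0), penumbra_mtt=(7.0, 7.0),
            penumbra_delay=(3.0, 3.0), core_cbf=(8.0, 8.0),
            core_mtt=(10.0, 10.0), core_delay=(6.0, 6.0),
            lesion_scale=(1.0, 1.0), half_coverage_rate=0.0,
        )
        cohort = build_cohort(2, 2, sampler, seed=5)
        params = {
            tuple((r.cbf_true, r.mtt_true, r.delay_true) for r in spec.regions)
            for _, _, spec in cohort
        }
        assert len(params) == 1  # identical parameters, only noise differs
        noise = {c[0].data.tobytes() for c in cohort}
        assert len(noise) == 4

    def test_empty_range_rejected(self):
        with pytest.raises(InvalidSpecError):
            CohortSampler(core_cbf=(12.0, 5.0))

    def test_needs_at_least_one_per_group(self):
        with pytest.raises(InvalidSpecError):
            build_cohort(0, 5)
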