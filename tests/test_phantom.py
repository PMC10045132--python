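"""Phantom generators: Z-spectra, GRE phase pairs, DWI stacks, cohorts."""

import numpy as np
import pandas as pd
import pytest

from aptdki.cest import compute_b0_map, mtr_asym, normalize_and_average
from aptdki.cohort import (
    CohortConfig,
    DEFAULT_CATEGORICAL_COUNTS,
    apply_patient_flow,
    generate_cohort,
    screening_flow,
)
from aptdki.phantom import (
    DEFAULT_WATER_POOL,
    LorentzianPool,
    PhantomTruth,
    simulate_dwi_stack,
    simulate_gre_phase_pair,
    simulate_zspectrum,
    true_mtr_asym,
    wrap_phase,
    zspectrum_model,
)


class TestZSpectrumSimulation:
    def test_no_pools_gives_unit_spectrum(self, scheme):
        frames = simulate_zspectrum([], scheme, noise_sd=0.0, s0=1.0)
        assert np.allclose(frames, 1.0)

    def test_water_only_spectrum_is_symmetric(self, scheme):
        frames = simulate_zspectrum([DEFAULT_WATER_POOL], scheme, noise_sd=0.0)
        zs = normalize_and_average(frames, scheme)
        for w in zs.offsets_ppm[zs.offsets_ppm > 0]:
            if -w in zs.offsets_ppm:
                assert zs.value_at(w) == pytest.approx(zs.value_at(-w), abs=1e-12)
        assert mtr_asym(zs) == pytest.approx(0.0, abs=1e-12)

    def test_amide_pool_recovered_by_mtr_asym(self, scheme):
        # analytic oracle: difference of the Lorentzian sums at +/-3.5 ppm
        amide = LorentzianPool(3.5, 0.10, 1.0)
        pools = [DEFAULT_WATER_POOL, amide]
        expected = float(
            zspectrum_model(pools, [-3.5])[0] - zspectrum_model(pools, [3.5])[0]
        )
        assert expected == pytest.approx(0.10, abs=0.005)  # near-full amide depth
        frames = simulate_zspectrum(pools, scheme, noise_sd=0.0)
        zs = normalize_and_average(frames, scheme)
        assert mtr_asym(zs) == pytest.approx(expected, abs=1e-10)

    def test_z_values_stay_in_unit_interval(self, scheme, rng):
        for _ in range(20):
            amp = rng.uniform(0, 0.1)
            b0 = rng.uniform(-0.8, 0.8)
            frames = simulate_zspectrum(
                [DEFAULT_WATER_POOL, LorentzianPool(3.5, amp, 1.4)],
                scheme, b0_shift_ppm=b0, noise_sd=0.0, s0=1.0)
            assert np.all(frames >= 0.0) and np.all(frames <= 1.0)

    def test_oversaturated_pools_rejected(self, scheme):
        pools = [LorentzianPool(0.0, 0.9, 3.0), LorentzianPool(0.2, 0.5, 3.0)]
        with pytest.raises(ValueError, match="sum"):
            simulate_zspectrum(pools, scheme)

    def test_repeated_offsets_get_independent_noise(self, scheme):
        rng = np.random.default_rng(0)
        frames = simulate_zspectrum([DEFAULT_WATER_POOL], scheme,
                                    noise_sd=0.01, rng=rng)
        offs = scheme.frame_offsets()
        at_35 = [frames[i] for i, w in enumerate(offs) if w == 3.5]
        assert len(set(at_35)) == len(at_35)

    def test_pool_validation(self):
        with pytest.raises(ValueError):
            LorentzianPool(3.5, 1.5, 1.0)
        with pytest.raises(ValueError):
            LorentzianPool(3.5, 0.5, -1.0)


class TestGrePhasePair:
    def test_zero_field_gives_zero_phase_difference(self):
        pair = simulate_gre_phase_pair(np.zeros((4, 4)))
        assert np.allclose(wrap_phase(pair.phase_late - pair.phase_early), 0.0)

    def test_phase_difference_matches_closed_form(self):
        # 2*pi * (0.0253 ppm * 127.74 MHz) * 4.92 ms ~ 0.1 rad
        b0 = np.array([0.0253])
        expected = 2 * np.pi * (0.0253 * 127.74) * 0.00492
        pair = simulate_gre_phase_pair(b0, te_delta_ms=4.92, larmor_mhz=127.74)
        dphi = wrap_phase(pair.phase_late - pair.phase_early)
        assert dphi[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0999, abs=1e-3)

    @pytest.mark.parametrize("b0_ppm", [-0.7, -0.3, 0.0, 0.1, 0.5, 0.79])
    def test_round_trip_below_wrap_limit(self, b0_ppm):
        # wrap limit: 1/(2*4.92ms) = 101.6 Hz = 0.7955 ppm at 127.74 MHz
        field = np.full((3, 3), b0_ppm)
        pair = simulate_gre_phase_pair(field)
        b0 = compute_b0_map(pair.phase_early, pair.phase_late,
                            pair.te_delta_ms, pair.larmor_mhz)
        assert np.max(np.abs(b0.b0_ppm - field)) < 1e-10
        assert not pair.wrapped.any()

    def test_wrapped_voxels_flagged(self):
        pair = simulate_gre_phase_pair(np.array([0.9]))  # beyond 0.7955 ppm
        assert pair.wrapped.all()

    def test_receiver_phase_cancels_in_difference(self):
        field = np.full((2, 2), 0.2)
        base = np.array([[0.5, -2.0], [3.0, 1.0]])
        pair = simulate_gre_phase_pair(field, base_phase=base)
        b0 = compute_b0_map(pair.phase_early, pair.phase_late,
                            pair.te_delta_ms, pair.larmor_mhz)
        assert np.allclose(b0.b0_ppm, field, atol=1e-10)

    def test_nonpositive_te_delta_rejected(self):
        with pytest.raises(ValueError):
            simulate_gre_phase_pair(np.zeros(2), te_delta_ms=0.0)


class TestDwiSimulation:
    def _truth(self, md=1.0, mk=0.9, s0=100.0):
        one = np.ones((2, 2))
        return PhantomTruth(s0=s0 * one, md_e3=md * one, mk=mk * one)

    def test_signal_matches_kurtosis_model(self):
        # S = 100 * exp(-2 + 0.6) at b = 2000, MD = 1e-3, MK = 0.9
        stack = simulate_dwi_stack(self._truth(), [0.0, 2000.0])
        assert stack[0, 0, 1] == pytest.approx(100 * np.exp(-2 + 0.6), rel=1e-12)
        assert stack[0, 0, 1] == pytest.approx(24.66, abs=0.005)

    def test_zero_kurtosis_is_monoexponential(self):
        b = np.array([0.0, 500.0, 1000.0, 2000.0])
        stack = simulate_dwi_stack(self._truth(mk=0.0), b)
        assert np.allclose(stack[0, 0], 100 * np.exp(-b * 1e-3))

    def test_b0_returns_s0(self):
        stack = simulate_dwi_stack(self._truth(), [0.0, 1000.0])
        assert np.allclose(stack[..., 0], 100.0)

    def test_negative_b_rejected(self):
        with pytest.raises(ValueError):
            simulate_dwi_stack(self._truth(), [-100.0, 0.0])

    def test_missing_b0_rejected(self):
        with pytest.raises(ValueError):
            simulate_dwi_stack(self._truth(), [500.0, 1000.0])

    def test_rician_noise_is_nonnegative_and_biased_up_at_high_b(self):
        rng = np.random.default_rng(0)
        truth = PhantomTruth(s0=np.full(4000, 100.0),
                             md_e3=np.full(4000, 2.5), mk=np.zeros(4000))
        stack = simulate_dwi_stack(truth, [0.0, 2000.0], noise_sigma=5.0, rng=rng)
        assert np.all(stack >= 0)
        clean = 100 * np.exp(-2000 * 2.5e-3)
        # magnitude noise inflates the mean where signal ~ noise floor
        assert stack[:, 1].mean() > clean


class TestCohortGeneration:
    def test_group_sizes_and_crosstabs_exact(self, cohort):
        assert len(cohort) == 61
        assert cohort.lnm.sum() == 17
        assert (cohort.lnm == 0).sum() == 44
        ct = pd.crosstab(cohort.depth_deep, cohort.lnm)
        assert ct.loc[1, 1] == 16 and ct.loc[0, 1] == 1
        assert ct.loc[1, 0] == 18 and ct.loc[0, 0] == 26
        for col, (k_non, k_lnm) in DEFAULT_CATEGORICAL_COUNTS.items():
            assert cohort[cohort.lnm == 0][col].sum() == k_non, col
            assert cohort[cohort.lnm == 1][col].sum() == k_lnm, col

    def test_seed_reproducibility(self):
        a = generate_cohort(seed=42)
        b = generate_cohort(seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(seed=43)
        assert not a.drop(columns="patient_id").equals(c.drop(columns="patient_id"))

    def test_large_sample_marker_means_converge(self):
        cfg = CohortConfig(
            n_lnm=20000, n_non_lnm=20000,
            categorical_counts={k: (10000, 10000)
                                for k in DEFAULT_CATEGORICAL_COUNTS})
        df = generate_cohort(cfg, seed=0)
        lnm = df[df.lnm == 1]
        se = 1.1 / np.sqrt(len(lnm))
        assert abs(lnm.aptw.mean() - 3.7) < 3 * se
        non = df[df.lnm == 0]
        assert abs(non.md.mean() - 1.193) < 3 * (0.337 / np.sqrt(len(non)))

    def test_copula_correlation_respected(self):
        corr = np.array([[1.0, 0.6, -0.4], [0.6, 1.0, -0.3], [-0.4, -0.3, 1.0]])
        cfg = CohortConfig(
            n_lnm=5000, n_non_lnm=5000, marker_corr=corr,
            categorical_counts={k: (2500, 2500)
                                for k in DEFAULT_CATEGORICAL_COUNTS})
        df = generate_cohort(cfg, seed=1)
        sub = df[df.lnm == 1][["aptw", "mk", "md"]]
        est = np.corrcoef(sub.to_numpy().T)
        assert np.max(np.abs(est - corr)) < 0.05

    def test_infeasible_counts_rejected(self):
        cfg = CohortConfig(categorical_counts={
            **DEFAULT_CATEGORICAL_COUNTS, "depth_deep": (18, 99)})
        with pytest.raises(ValueError, match="infeasible"):
            generate_cohort(cfg)

    def test_age_and_size_respect_ranges(self, cohort):
        assert cohort.age.between(28, 78).all()
        assert cohort.tumor_size_mm.between(13, 105).all()


class TestPatientFlow:
    def test_default_flow_keeps_61_of_105(self):
        ledger = screening_flow()
        assert len(ledger) == 105
        included = apply_patient_flow(ledger)
        assert len(included) == 61
        counts = ledger.status.value_counts()
        assert counts["incomplete_histopathology"] == 21
        assert counts["non_cervical_cancer"] == 9
        assert counts["tumor_under_10mm"] == 10
        assert counts["inadequate_image_quality"] == 4

    def test_overfull_exclusions_rejected(self):
        with pytest.raises(ValueError):
            screening_flow(n_screened=10, exclusions=(("a", 11),))
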