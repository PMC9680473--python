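"""Synthetic cohort generator: sampling statistics, forward models, noise."""

import numpy as np
import pytest
from scipy import integrate, interpolate

from ivimdce.cohort import (
    CohortConfig,
    add_rician,
    dce_forward,
    dwi_forward,
    generate_cohort,
    generate_summary_cohort,
    sample_lesion_truth,
    simulate_readers,
)
from ivimdce.agreement import icc_table
from ivimdce.diffusion import DWISignal
from ivimdce.tofts import etm_forward_batch


class TestLesionSampling:
    def test_malignant_d_matches_group_mean_and_sd(self, rng):
        draws = np.array([sample_lesion_truth("malignant", rng).D
                          for _ in range(10_000)])
        assert np.mean(draws) == pytest.approx(1.07e-3, abs=0.01e-3)
        assert np.std(draws) == pytest.approx(0.26e-3, abs=0.01e-3)

    def test_malignant_f_median_matches_lognormal(self, rng):
        # The matched log-normal's median is the printed group median.
        draws = np.array([sample_lesion_truth("malignant", rng).f
                          for _ in range(10_000)])
        assert np.median(draws) * 100 == pytest.approx(13.70, abs=0.25)

    def test_zero_width_collapses_to_central_values(self, rng):
        t = sample_lesion_truth("benign", rng, width_scale=0.0)
        assert t.D == pytest.approx(1.41e-3)
        assert t.Dstar == pytest.approx(27.05e-3)
        assert t.f == pytest.approx(0.11)
        assert t.kep == pytest.approx(0.31)
        assert t.Ktrans == pytest.approx(0.31 * 0.73)

    def test_invariants_hold_across_draws(self, rng):
        for _ in range(500):
            t = sample_lesion_truth("benign", rng)
            assert 0 < t.D <= t.Dstar
            assert 0.0 <= t.f <= 1.0
            assert t.kep > 0 and t.Ktrans >= 0
            assert 0.0 <= t.ve <= 1.0

    def test_unknown_group_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown group"):
            sample_lesion_truth("suspicious", rng)


class TestDWIForward:
    def test_b0_returns_s0_exactly(self, malignant_truth):
        sig = dwi_forward(malignant_truth, S0=1234.0)
        assert sig.array[0] == pytest.approx(1234.0, rel=1e-14)

    def test_mono_exponential_limit(self, rng):
        t = sample_lesion_truth("malignant", rng)
        t = type(t)(lesion_id="m", group="malignant", D=1.0e-3, Dstar=1.0e-3,
                    f=0.0, Ktrans=t.Ktrans, kep=t.kep, vp=t.vp)
        sig = dwi_forward(t, S0=1000.0)
        assert sig.array[-1] == pytest.approx(1000.0 * np.exp(-0.8), rel=1e-12)

    def test_reference_parameters_match_scalar_arithmetic(self, malignant_truth):
        # Independent scalar evaluation of the bi-exponential at b=100.
        sig = dwi_forward(malignant_truth, S0=1000.0)
        b = 100.0
        expected = 1000.0 * ((1 - 0.137) * np.exp(-b * 1.07e-3)
                             + 0.137 * np.exp(-b * (1.07e-3 + 15.20e-3)))
        idx = list(sig.scheme.b_values).index(b)
        assert sig.array[idx] == pytest.approx(expected, rel=1e-14)

    def test_noiseless_signal_decreases_with_b(self, rng):
        for _ in range(50):
            t = sample_lesion_truth("benign", rng)
            s = dwi_forward(t).array
            assert np.all(s > 0)
            assert np.all(np.diff(s) < 0)


class TestDCEForward:
    def test_no_tracer_exchange_gives_zero_curve(self, cp, malignant_truth):
        t = type(malignant_truth)(lesion_id="z", group="malignant", D=1e-3,
                                  Dstar=15e-3, f=0.1, Ktrans=0.0, kep=1.0, vp=0.0)
        assert np.all(dce_forward(t, cp).array == 0.0)

    def test_pure_plasma_term(self, cp, malignant_truth):
        t = type(malignant_truth)(lesion_id="p", group="malignant", D=1e-3,
                                  Dstar=15e-3, f=0.1, Ktrans=0.0, kep=1.0, vp=0.05)
        assert np.allclose(dce_forward(t, cp).array, 0.05 * cp.array, atol=1e-14)

    def test_baseline_frames_are_zero(self, cp, malignant_truth):
        ct = dce_forward(malignant_truth, cp).array
        assert np.all(ct[:cp.grid.injection_frame - 1] == 0.0)

    def test_convolution_agrees_with_quadrature_oracle(self, cp, malignant_truth):
        """The exponential-kernel recursion matches adaptive quadrature of
        the convolution integral (piecewise-linear Cp) to <0.1%."""
        grid = cp.grid
        t_min = grid.times_min
        cp_lin = interpolate.interp1d(t_min, cp.array, kind="linear")
        truth = malignant_truth
        ct = dce_forward(truth, cp).array
        for k in (10, 25, 41):
            tk = t_min[k]
            conv, _ = integrate.quad(
                lambda tau: cp_lin(tau) * np.exp(-truth.kep * (tk - tau)),
                0.0, tk, limit=400)
            expected = truth.vp * cp.array[k] + truth.Ktrans * conv
            assert ct[k] == pytest.approx(expected, rel=1e-3)

    def test_nonpositive_kep_rejected_at_construction(self, malignant_truth):
        with pytest.raises(ValueError):
            type(malignant_truth)(lesion_id="b", group="benign", D=1e-3,
                                  Dstar=15e-3, f=0.1, Ktrans=0.5, kep=0.0,
                                  vp=0.02)


class TestRicianNoise:
    def test_zero_sigma_is_identity(self, malignant_truth, rng):
        sig = dwi_forward(malignant_truth)
        assert add_rician(sig, 0.0, rng) is sig

    def test_zero_signal_gives_rayleigh_mean(self, scheme, rng):
        # |N(0,s) + i N(0,s)| has mean s sqrt(pi/2).
        sig = DWISignal.from_arrays(np.full(9, 1e-9), scheme)
        draws = np.concatenate([add_rician(sig, 1.0, rng).array
                                for _ in range(12_000)])
        assert np.mean(draws) == pytest.approx(np.sqrt(np.pi / 2), rel=0.01)

    def test_high_snr_limit_is_gaussian(self, scheme, rng):
        sig = DWISignal.from_arrays(np.full(9, 1000.0), scheme)
        draws = np.concatenate([add_rician(sig, 10.0, rng).array
                                for _ in range(4000)])
        assert np.std(draws) == pytest.approx(10.0, rel=0.03)

    def test_negative_sigma_rejected(self, malignant_truth, rng):
        with pytest.raises(ValueError):
            add_rician(dwi_forward(malignant_truth), -1.0, rng)


class TestCohortGeneration:
    def test_label_split_matches_config(self, small_config):
        cohort = generate_cohort(small_config)
        counts = cohort.truth["group"].value_counts()
        assert counts["benign"] == 6 and counts["malignant"] == 14

    def test_same_seed_reproduces_identical_bytes(self, small_config):
        a = generate_cohort(small_config)
        b = generate_cohort(small_config)
        assert a.truth.to_csv() == b.truth.to_csv()
        for lid in a.dwi_signals:
            assert np.array_equal(a.dwi_signals[lid], b.dwi_signals[lid])
            assert np.array_equal(a.dce_curves[lid], b.dce_curves[lid])

    def test_zero_intra_cv_makes_roi_degenerate(self):
        cfg = CohortConfig(n_benign=2, n_malignant=2, n_voxels=8, seed=5,
                           intra_cv=0.0, rician_sigma=0.0, conc_sigma=0.0)
        df = generate_summary_cohort(cfg)
        for family in ("D", "f", "Kep"):
            assert np.allclose(df[f"{family}_min"], df[f"{family}_max"])
            assert np.allclose(df[f"{family}_min"], df[f"{family}_mean"])

    def test_batched_curves_match_scalar_forward(self, cp, malignant_truth):
        ct_batch = etm_forward_batch(
            np.array([malignant_truth.Ktrans]), np.array([malignant_truth.kep]),
            np.array([malignant_truth.vp]), cp)[0]
        ct_scalar = dce_forward(malignant_truth, cp).array
        assert np.allclose(ct_batch, ct_scalar, atol=1e-14)


class TestReaderSimulation:
    def test_target_icc_is_reproduced(self, rng):
        # Large-sample check of the noise calibration: target 0.5.
        cfg = CohortConfig(n_benign=100, n_malignant=100, n_voxels=4, seed=2)
        df = generate_summary_cohort(cfg, rng=rng)
        readers = simulate_readers(df, rng, target_icc={c: 0.5 for c in df.columns
                                                        if c not in ("lesion_id", "group")})
        reports = {r.parameter: r.icc for r in icc_table(readers)}
        iccs = np.array(list(reports.values()))
        assert abs(np.mean(iccs) - 0.5) < 0.05

    def test_perfect_agreement_when_icc_one(self, rng, small_config):
        df = generate_summary_cohort(small_config, rng=rng)
        readers = simulate_readers(df, rng, target_icc={})  # default 1.0
        wide = readers.pivot_table(index=["lesion_id", "parameter"],
                                   columns="reader", values="value")
        assert np.allclose(wide[1], wide[2])
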