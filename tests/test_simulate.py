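"""Simulator behaviour: continuous models, count noise, cohort pairing."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.signal import fftconvolve

from lowpet.framing import apply_scheme, make_full_schedule, make_scheme
from lowpet.simulate import (
    TRACER_PRESETS,
    CohortConfig,
    InputFunctionParams,
    KineticParams,
    NoiseModel,
    ReferenceKinetics,
    bin_counts,
    exp_conv,
    fine_grid_s,
    make_cohort,
    plasma_input,
    reference_tac,
    srtm_forward,
    thin_counts,
)


class TestPlasmaInput:
    def test_zero_at_and_before_onset(self):
        p = InputFunctionParams()
        assert plasma_input(p.t0, p) == 0.0
        assert np.all(plasma_input(np.linspace(0, p.t0, 20), p) == 0.0)

    def test_decays_to_zero_at_late_times(self):
        p = InputFunctionParams()
        assert plasma_input(1e4, p) < 1e-6 * plasma_input(1.0, p)

    def test_non_negative_everywhere(self):
        t = np.linspace(0, 90, 20000)
        assert np.all(plasma_input(t) >= 0)

    def test_peak_against_dense_evaluation_oracle(self):
        # Peak located on a 1 ms grid must agree with the analytic function.
        p = InputFunctionParams()
        t_dense = np.arange(0, 5 * 60000) * 1e-3 / 60.0  # minutes, 1 ms steps
        vals = plasma_input(t_dense, p)
        i = int(np.argmax(vals))
        assert vals[i] == pytest.approx(float(plasma_input(t_dense[i], p)), rel=1e-12)
        # coarse re-evaluation brackets the same peak
        assert abs(t_dense[i] - p.t0 - 1.0 / abs(p.l1)) < 0.05  # analytic max of t*e^{l1 t}

    def test_rate_sign_validation(self):
        with pytest.raises(ValueError):
            InputFunctionParams(l1=0.1)


class TestReferenceTac:
    def test_zero_uptake_gives_zero_curve(self):
        t = np.linspace(0, 90, 200)
        out = reference_tac(InputFunctionParams(), ReferenceKinetics(K1p=0.0, k2p=0.1), t)
        assert np.all(out == 0)

    def test_constant_input_steady_state(self):
        # One-tissue model with constant input c approaches K1/k2 * c.
        c, k = 7.0, 0.3
        t = np.linspace(0, 200, 12001)
        conv = exp_conv(np.full_like(t, c), k, t[1] - t[0])
        assert conv[-1] * k == pytest.approx(c, rel=1e-6)

    def test_matches_stiff_ode_oracle(self):
        p, rk = InputFunctionParams(), ReferenceKinetics()
        times = np.linspace(1.0, 90.0, 30)
        ours = reference_tac(p, rk, times)

        def rhs(t, y):
            return [rk.K1p * float(plasma_input(t, p)) - rk.k2p * y[0]]

        sol = solve_ivp(rhs, (0, 90.0), [0.0], t_eval=times, method="LSODA",
                        rtol=1e-10, atol=1e-12, max_step=0.25)
        assert np.allclose(ours, sol.y[0], rtol=1e-3)  # 0.1 %


class TestSrtmForward:
    def test_unit_r1_zero_bp_reproduces_reference(self, fine_time_min, default_reference_fine):
        kp = KineticParams(r1=1.0, k2=0.3, bp_nd=0.0)
        ct = srtm_forward(default_reference_fine, kp, fine_time_min)
        assert np.allclose(ct, default_reference_fine, rtol=0, atol=1e-12)

    def test_zero_reference_gives_zero_target(self, fine_time_min):
        kp = KineticParams(r1=1.0, k2=0.3, bp_nd=2.0)
        ct = srtm_forward(np.zeros_like(fine_time_min), kp, fine_time_min)
        assert np.all(ct == 0)

    def test_matches_trapezoidal_convolution_oracle(self):
        # Independent oracle: FFT-based trapezoidal convolution at 0.1 s steps.
        p, rk = InputFunctionParams(), ReferenceKinetics()
        dt_min = 0.1 / 60.0
        t = np.arange(0, int(5400 / 0.1) + 1) * dt_min
        cr = rk.K1p * exp_conv(plasma_input(t, p), rk.k2p, dt_min)
        kp = KineticParams(r1=1.0, k2=0.3, bp_nd=2.0)
        ours = srtm_forward(cr, kp, t)
        kern = np.exp(-kp.k2a * t)
        conv = fftconvolve(cr, kern)[: t.size] * dt_min
        conv -= 0.5 * dt_min * (cr[0] * kern + cr * kern[0])  # trapezoid ends
        oracle = kp.r1 * cr + (kp.k2 - kp.r1 * kp.k2a) * conv
        sel = t > 1.0
        assert np.allclose(ours[sel], oracle[sel], rtol=1e-3)


class TestBinCounts:
    def _frames(self, label):
        return apply_scheme(make_full_schedule(), make_scheme(label))

    def test_constant_activity_no_decay_counts_are_exact(self):
        nm = NoiseModel(sensitivity=3.0, decay_lambda_per_s=0.0, mode="expected")
        tac = bin_counts(lambda t: np.full_like(np.asarray(t, float), 5.0), self._frames("full"), nm)
        assert np.allclose(tac.counts, 3.0 * 5.0 * tac.durations_s, rtol=0, atol=1e-9)
        assert np.allclose(tac.conc, 5.0)

    @pytest.mark.parametrize("label,frac", [("1/3", 1 / 3), ("1/5", 1 / 5)])
    def test_exact_fraction_rows_scale_expected_counts(self, label, frac):
        nm = NoiseModel(sensitivity=2.0, decay_lambda_per_s=0.0, mode="expected")
        const = lambda t: np.full_like(np.asarray(t, float), 4.0)
        full = bin_counts(const, self._frames("full"), nm)
        low = bin_counts(const, self._frames(label), nm)
        assert np.allclose(low.counts, frac * full.counts, rtol=1e-12)

    def test_seeded_draws_are_reproducible(self):
        const = lambda t: np.full_like(np.asarray(t, float), 8.0)
        a = bin_counts(const, self._frames("1/2"), NoiseModel(seed=7))
        b = bin_counts(const, self._frames("1/2"), NoiseModel(seed=7))
        c = bin_counts(const, self._frames("1/2"), NoiseModel(seed=8))
        assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            bin_counts(lambda t: np.asarray(t, float) - 100.0, self._frames("full"), NoiseModel())

    def test_decay_corrected_estimate_is_unbiased_for_constant_activity(self):
        # Monte-Carlo mean of the recovered concentration -> truth within 3 SE.
        nm = NoiseModel(sensitivity=0.5)
        frames = self._frames("1/4")
        rng = np.random.default_rng(42)
        const = lambda t: np.full_like(np.asarray(t, float), 6.0)
        reps = np.array([bin_counts(const, frames, nm, rng=rng).conc.mean() for _ in range(300)])
        se = reps.std(ddof=1) / np.sqrt(reps.size)
        assert abs(reps.mean() - 6.0) < 3 * se

    def test_relative_noise_grows_as_retained_counts_shrink(self):
        # SD/mean of the recovered concentration must be monotone in 1/f.
        rng = np.random.default_rng(3)
        const = lambda t: np.full_like(np.asarray(t, float), 6.0)
        nm = NoiseModel(sensitivity=0.5)
        noise = []
        for lab in ["full", "1/3", "1/15"]:
            frames = self._frames(lab)
            vals = np.array([bin_counts(const, frames, nm, rng=rng).conc[-1] for _ in range(200)])
            noise.append(vals.std(ddof=1) / vals.mean())
        assert noise[0] < noise[1] < noise[2]


class TestThinCounts:
    def test_identity_and_zero_limits(self):
        counts = np.array([0, 5, 1000])
        assert np.array_equal(thin_counts(counts, 1.0, 0), counts)
        assert np.array_equal(thin_counts(counts, 0.0, 0), np.zeros(3))

    def test_monte_carlo_mean_matches_binomial(self):
        rng = np.random.default_rng(11)
        draws = thin_counts(np.full(10_000, 1000), 0.5, rng)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 500.0) < 3 * se

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            thin_counts([1, 2], 1.5, 0)
        with pytest.raises(ValueError):
            thin_counts([-1], 0.5, 0)


class TestMakeCohort:
    def test_cohort_shape_and_pairing(self):
        cohort = make_cohort("UCBJ", 2, ["full", "1/2", "1/15"], NoiseModel(seed=5))
        assert set(cohort) == {"full", "1/2", "1/15"}
        for lab, datasets in cohort.items():
            assert len(datasets) == 2
            for ds in datasets:
                assert ds.reference_region == "centrum_semiovale"
                assert len(ds.tacs) == 14  # 13 targets + pseudo-reference
        # Pairing: identical truth across schemes, and truncated counts can
        # never exceed the full-frame counts they are a subset of.
        for i in range(2):
            t_full = cohort["full"][i].truth
            for lab in ("1/2", "1/15"):
                assert cohort[lab][i].truth == t_full
                for region in t_full:
                    assert np.all(
                        cohort[lab][i].tacs[region].counts
                        <= cohort["full"][i].tacs[region].counts + 1e-9
                    )

    def test_phno_preset_regions(self):
        cohort = make_cohort("PHNO", 2, ["full"], NoiseModel(seed=1))
        ds = cohort["full"][0]
        assert ds.reference_region == "cerebellum"
        assert set(ds.tacs) == set(TRACER_PRESETS["PHNO"].regions)

    def test_noise_free_full_scheme_matches_forward_model(
        self, fine_time_min, default_reference_fine
    ):
        nm = NoiseModel(mode="none", seed=0)
        cfg = CohortConfig(
            bp_jitter_cv=0, r1_jitter_cv=0, k2_jitter_cv=0, vary_injected_activity=False
        )
        ds = make_cohort("PHNO", 2, ["full"], nm, cfg)["full"][0]
        truth = TRACER_PRESETS["PHNO"].truth["striatum"]
        ct = srtm_forward(default_reference_fine, truth, fine_time_min)
        tac = ds.tacs["striatum"]
        expect = np.interp(tac.midtimes_s / 60.0, fine_time_min, ct)
        assert np.allclose(tac.conc, expect, rtol=1e-3)

    def test_same_seed_reproduces_cohort_exactly(self):
        a = make_cohort("PHNO", 2, ["1/4"], NoiseModel(seed=9))["1/4"]
        b = make_cohort("PHNO", 2, ["1/4"], NoiseModel(seed=9))["1/4"]
        for da, db in zip(a, b):
            for region in da.tacs:
                assert np.array_equal(da.tacs[region].conc, db.tacs[region].conc)

    def test_unknown_tracer_and_tiny_cohort_rejected(self):
        with pytest.raises(ValueError, match="tracer"):
            make_cohort("FDG", 3)
        with pytest.raises(ValueError, match="2 subjects"):
            make_cohort("PHNO", 1)


class TestTruncationVsThinning:
    def test_expectations_agree_for_constant_activity_exact_fractions(self):
        # For constant activity and no decay the truncation simulator and the
        # binomial-thinning oracle share the same mean counts at exact rows.
        nm_exp = NoiseModel(sensitivity=2.0, decay_lambda_per_s=0.0, mode="expected")
        const = lambda t: np.full_like(np.asarray(t, float), 10.0)
        sched = make_full_schedule()
        full = bin_counts(const, apply_scheme(sched, make_scheme("full")), nm_exp)
        for lab, frac in [("1/3", 1 / 3), ("1/5", 1 / 5)]:
            trunc = bin_counts(const, apply_scheme(sched, make_scheme(lab)), nm_exp)
            thin_mean = frac * full.counts  # Binomial(N, f) mean
            assert np.allclose(trunc.counts, thin_mean, rtol=1e-12)
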