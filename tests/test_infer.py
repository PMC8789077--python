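import numpy as np
import pytest

from rnacat.infer import fit_full_model, fit_mm, fit_uncompetitive
from rnacat.model import KineticParams
from rnacat.synth import NoiseSpec, generate_assay

S_GRID = np.array([2.0, 5.0, 10.0, 25.0, 50.0])


def _mm_v(k_cat, Km, s, c):
    return k_cat * c * s / (Km + s)


class TestFitMM:
    def test_noiseless_exact_recovery(self):
        c = np.ones_like(S_GRID)
        v = _mm_v(0.8, 22.0, S_GRID, c)
        r = fit_mm(v, S_GRID, c)
        assert r.k_cat == pytest.approx(0.8, abs=1e-8)
        assert r.Km == pytest.approx(22.0, abs=1e-7)

    def test_half_saturation_midpoint(self):
        c = np.ones_like(S_GRID)
        r = fit_mm(_mm_v(0.8, 22.0, S_GRID, c), S_GRID, c)
        v_at_km = _mm_v(r.k_cat, r.Km, r.Km, 1.0)
        assert v_at_km == pytest.approx(r.k_cat / 2.0, rel=1e-8)

    def test_scale_equivariance(self):
        c = np.full(S_GRID.size, 0.4)
        v = _mm_v(0.8, 22.0, S_GRID, c)
        base = fit_mm(v, S_GRID, c)
        scaled = fit_mm(3.7 * v, S_GRID, 3.7 * c)
        assert scaled.Km == pytest.approx(base.Km, rel=1e-8)
        assert scaled.k_cat == pytest.approx(base.k_cat, rel=1e-8)

    def test_flat_design_is_an_error(self):
        s = np.full(5, 10.0)
        with pytest.raises(ValueError):
            fit_mm(np.ones(5), s, np.ones(5))

    def test_noisy_recovery_median_within_15pct(self):
        rng = np.random.default_rng(7)
        c = np.ones_like(S_GRID)
        truth = _mm_v(0.8, 22.0, S_GRID, c)
        ks, kms = [], []
        for _ in range(50):
            v = truth * (1.0 + 0.05 * rng.standard_normal(truth.size))
            r = fit_mm(v, S_GRID, c)
            ks.append(r.k_cat)
            kms.append(r.Km)
        assert abs(np.median(ks) - 0.8) / 0.8 < 0.15
        assert abs(np.median(kms) - 22.0) / 22.0 < 0.15


class TestFitUncompetitive:
    def test_no_product_reduces_to_mm(self):
        c = np.ones_like(S_GRID)
        v = _mm_v(0.8, 22.0, S_GRID, c)
        r = fit_uncompetitive(v, S_GRID, np.zeros_like(S_GRID), c)
        assert not r.ki_defined and np.isnan(r.Ki)
        base = fit_mm(v, S_GRID, c)
        assert r.k_cat == pytest.approx(base.k_cat, rel=1e-10)
        assert r.Km == pytest.approx(base.Km, rel=1e-10)

    def test_noiseless_exact_recovery_with_ki(self):
        s = np.tile(S_GRID, 3)
        p = np.repeat([0.0, 5.0, 15.0], S_GRID.size)
        c = np.ones_like(s)
        v = 0.8 * c * s / (22.0 + s * (1.0 + p / 20.0))
        r = fit_uncompetitive(v, s, p, c)
        assert r.ki_defined
        assert r.k_cat == pytest.approx(0.8, rel=1e-6)
        assert r.Km == pytest.approx(22.0, rel=1e-6)
        assert r.Ki == pytest.approx(20.0, rel=1e-6)

    def test_saturating_velocity_depressed_by_product(self):
        """At s -> inf the uncompetitive law tends to Vmax/(1+p/Ki)."""
        s = np.array([1e5, 2e5, 4e5, 8e5])
        for p_level in (0.0, 10.0, 40.0):
            v = 0.8 * s / (22.0 + s * (1.0 + p_level / 20.0))
            assert v[-1] == pytest.approx(
                0.8 / (1.0 + p_level / 20.0), rel=1e-4
            )

    def test_weak_inhibition_limit_matches_mm(self):
        s = np.tile(S_GRID, 2)
        p = np.repeat([0.0, 10.0], S_GRID.size)
        c = np.ones_like(s)
        v = 0.8 * c * s / (22.0 + s * (1.0 + p / 1e9))  # Ki -> infinity
        r = fit_uncompetitive(v, s, p, c)
        base = fit_mm(v, s, c)
        assert r.k_cat == pytest.approx(base.k_cat, rel=1e-6)
        assert r.Km == pytest.approx(base.Km, rel=1e-6)


class TestFullModel:
    def test_noiseless_recovery_of_floated_parameters(
        self, paper_params, conditions, noiseless_assay
    ):
        eq, kin = paper_params
        init_eq = eq.with_(Kcs=40.0)
        init_kin = KineticParams(k_cat=0.3, Km=22.0, Ki=20.0)
        res = fit_full_model(
            noiseless_assay.progress_curves(), conditions, init_eq, init_kin,
            ("k_cat", "Kcs"), n_starts=2, seed=5, max_step=0.5,
        )
        assert res.params["k_cat"] == pytest.approx(0.8, rel=0.05)
        assert res.params["Kcs"] == pytest.approx(22.0, rel=0.05)
        # MM stage agrees with the mechanistic constants at zero noise
        assert res.kinetic.k_cat == pytest.approx(0.8, rel=0.05)
        assert res.kinetic.Km == pytest.approx(22.0, rel=0.05)

    def test_single_parameter_reduction_is_exact(
        self, paper_params, conditions, noiseless_assay
    ):
        eq, kin = paper_params
        res = fit_full_model(
            noiseless_assay.progress_curves(), conditions, eq,
            KineticParams(k_cat=0.2, Km=22.0, Ki=20.0),
            ("k_cat",), n_starts=1, seed=0, max_step=0.5,
        )
        assert res.params["k_cat"] == pytest.approx(0.8, rel=1e-4)

    def test_objective_at_truth_bounds_multistart_solution(
        self, paper_params, conditions, noiseless_assay
    ):
        """On the noiseless fixture the truth attains (near-)zero rss, so
        no multi-start solution may do better than the truth's objective
        and the best fit must reach it."""
        eq, kin = paper_params
        res = fit_full_model(
            noiseless_assay.progress_curves(), conditions, eq.with_(Kcs=30.0),
            KineticParams(k_cat=0.5, Km=22.0, Ki=20.0),
            ("k_cat", "Kcs"), n_starts=2, seed=3, max_step=0.5,
        )
        assert res.rss <= 1e-4
        assert min(res.start_rss) == pytest.approx(res.rss)

    def test_fixed_seed_reproducibility(
        self, paper_params, conditions
    ):
        eq, kin = paper_params
        fix = generate_assay(eq, kin, noise=NoiseSpec(0.05, seed=9))
        out = []
        for _ in range(2):
            res = fit_full_model(
                fix.progress_curves(), conditions, eq,
                KineticParams(k_cat=0.3, Km=22.0, Ki=20.0),
                ("k_cat",), n_starts=2, seed=17, max_step=0.5,
            )
            out.append((res.params["k_cat"], res.rss))
        assert out[0] == out[1]

    def test_unknown_float_name_rejected(self, paper_params, conditions,
                                         noiseless_assay):
        eq, kin = paper_params
        with pytest.raises(ValueError):
            fit_full_model(noiseless_assay.progress_curves(), conditions,
                           eq, kin, ("Vmax",))
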