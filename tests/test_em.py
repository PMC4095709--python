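"""EM engine: responsibilities, closed-form updates, ascent, recovery."""

import numpy as np
import pytest

import diffmix as dm
from diffmix.em import _run_em_fast, weighted_loglik

from conftest import random_model


class TestEStep:
    def test_rows_sum_to_one_on_random_models(self, rng):
        for model_class in dm.core.MODEL_CLASSES:
            model = random_model(model_class, rng)
            data = dm.Dataset.from_arrays(rng.normal(0, 2, 300))
            resp = dm.e_step(model, data)
            assert np.all(resp >= 0)
            np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-12)

    def test_pi_zero_gives_no_f1_responsibility(self, rng):
        model = dm.MixtureModel(
            "iNUDGE", 0.0, [dm.NormalComponent(0, 1, 1.0)],
            dm.UniformComponent(-5, 5),
        )
        data = dm.Dataset.from_arrays(rng.uniform(-4, 4, 100))
        resp = dm.e_step(model, data)
        np.testing.assert_array_equal(resp[:, 1], 0.0)

    def test_single_live_component_takes_all(self, rng):
        model = dm.MixtureModel(
            "NUDGE", 0.0, [dm.NormalComponent(0, 1, 1.0)],
            dm.UniformComponent(-5, 5),
        )
        data = dm.Dataset.from_arrays(rng.normal(0, 1, 50))
        np.testing.assert_allclose(dm.e_step(model, data)[:, 0], 1.0)


class TestMStep:
    def test_two_point_closed_form(self):
        # all responsibility on the single normal: weighted mean/variance
        data = dm.Dataset.from_arrays(np.array([-1.0, 1.0]))
        model = dm.MixtureModel(
            "NUDGE", 0.5, [dm.NormalComponent(0.3, 2.0, 1.0)],
            dm.UniformComponent(-1.0, 1.0),
        )
        resp = np.array([[1.0, 0.0], [1.0, 0.0]])
        new = dm.m_step(resp, data, model)
        assert new.normals[0].mu == pytest.approx(0.0)
        assert new.normals[0].sigma2 == pytest.approx(1.0)
        assert new.pi == pytest.approx(0.0)

    def test_collapses_to_unweighted_mle(self, rng):
        y = rng.normal(1.7, 1.3, 400)
        data = dm.Dataset.from_arrays(y)
        model = dm.MixtureModel(
            "NUDGE", 0.0, [dm.NormalComponent(0, 1, 1.0)],
            dm.UniformComponent(float(y.min()), float(y.max())),
        )
        resp = np.column_stack([np.ones_like(y), np.zeros_like(y)])
        new = dm.m_step(resp, data, model)
        assert new.normals[0].mu == pytest.approx(y.mean())
        assert new.normals[0].sigma2 == pytest.approx(np.var(y))

    def test_update_invariant_to_weight_rescaling(self, rng):
        y = rng.normal(0, 1, 200)
        model = random_model("GNG", rng)
        half = dm.Dataset.from_arrays(y, w=np.full_like(y, 0.5))
        full = dm.Dataset.from_arrays(y, w=np.ones_like(y))
        resp = dm.e_step(model, full)
        a = dm.m_step(resp, half, model)
        b = dm.m_step(resp, full, model)
        np.testing.assert_allclose(a.mus, b.mus)
        np.testing.assert_allclose(a.sigma2s, b.sigma2s)
        assert a.pi == pytest.approx(b.pi)

    def test_responsibility_collapse_freezes_component(self, rng):
        y = rng.normal(0, 1, 100)
        data = dm.Dataset.from_arrays(y)
        model = dm.MixtureModel(
            "iNUDGE", 0.5,
            [dm.NormalComponent(0, 1, 0.5), dm.NormalComponent(30, 1, 0.5)],
            dm.UniformComponent(float(y.min()), float(y.max())),
        )
        resp = dm.e_step(model, data)
        warnings = []
        new = dm.m_step(resp, data, model, warnings)
        assert new.normals[1].mu == 30  # untouched
        assert any("frozen" in w for w in warnings)


class TestInitialize:
    def test_k1_uses_sample_moments(self, small_mixture_data):
        for method in ("kmeans", "quantile", "random"):
            m = dm.initialize("iNUDGE", 1, small_mixture_data, method, 0)
            assert m.normals[0].mu == pytest.approx(small_mixture_data.y.mean())
            assert m.normals[0].sigma2 == pytest.approx(
                np.var(small_mixture_data.y)
            )
            assert m.pi == 0.1

    def test_quantile_positions(self):
        data = dm.Dataset.from_arrays([-3.0, -1.0, 1.0, 3.0])
        m = dm.initialize("iNUDGE", 2, data, "quantile", 0)
        np.testing.assert_allclose(m.mus, [-1.0, 1.0])

    def test_reproducible_given_seed(self, small_mixture_data):
        a = dm.initialize("iNUDGE", 3, small_mixture_data, "random", 42)
        b = dm.initialize("iNUDGE", 3, small_mixture_data, "random", 42)
        np.testing.assert_array_equal(a.mus, b.mus)

    def test_k_exceeding_distinct_values_rejected(self):
        data = dm.Dataset.from_arrays([1.0, 1.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            dm.initialize("iNUDGE", 3, data, "quantile", 0)


class TestFit:
    def test_loglik_recomputes_from_model(self, small_mixture_data):
        fr = dm.fit("iNUDGE", 2, small_mixture_data, dm.FitConfig(seed=3))
        assert fr.loglik == pytest.approx(
            weighted_loglik(fr.model, small_mixture_data), abs=1e-8
        )
        assert fr.n_obs == small_mixture_data.n

    def test_monotone_ascent_via_reference_steps(self, two_sided_data):
        for model_class, K in [("NUDGE", 1), ("iNUDGE", 2), ("GNG", 2)]:
            model = dm.initialize(model_class, K, two_sided_data, "quantile", 0)
            prev = weighted_loglik(model, two_sided_data)
            for _ in range(25):
                resp = dm.e_step(model, two_sided_data)
                model = dm.m_step(resp, two_sided_data, model)
                cur = weighted_loglik(model, two_sided_data)
                assert cur >= prev - 1e-8
                prev = cur

    def test_fast_loop_matches_reference_steps(self, two_sided_data):
        for model_class, K in [("iNUDGE", 2), ("GNG", 3)]:
            start = dm.initialize(model_class, K, two_sided_data, "quantile", 0)
            cfg = dm.FitConfig(tol=1e-300, max_iter=7, seed=0)
            fast, *_ = _run_em_fast(start, two_sided_data, cfg, iter_cap=7)
            ref = start
            for _ in range(7):
                ref = dm.m_step(dm.e_step(ref, two_sided_data),
                                two_sided_data, ref)
            np.testing.assert_allclose(fast.mus, ref.mus, rtol=1e-9)
            np.testing.assert_allclose(fast.sigma2s, ref.sigma2s, rtol=1e-9)
            np.testing.assert_allclose(fast.gammas, ref.gammas, rtol=1e-9)
            assert fast.pi == pytest.approx(ref.pi, rel=1e-9)

    def test_nesting_inudge_k1_equals_nudge(self, small_mixture_data):
        cfg = dm.FitConfig(seed=5)
        a = dm.fit("NUDGE", 1, small_mixture_data, cfg)
        b = dm.fit("iNUDGE", 1, small_mixture_data, cfg)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-6)

    def test_deterministic_given_seed(self, two_sided_data):
        cfg = dm.FitConfig(seed=11)
        a = dm.fit("GNG", 2, two_sided_data, cfg)
        b = dm.fit("GNG", 2, two_sided_data, cfg)
        np.testing.assert_array_equal(a.model.mus, b.model.mus)
        np.testing.assert_array_equal(a.model.sigma2s, b.model.sigma2s)
        assert a.loglik == b.loglik and a.n_iter == b.n_iter

    def test_too_few_observations_rejected(self):
        data = dm.Dataset.from_arrays([-1.0, 0.5, 1.0, -0.2])
        with pytest.raises(ValueError, match="parameters"):
            dm.fit("GNG", 2, data, dm.FitConfig())

    def test_gng_one_sided_data_rejected(self):
        data = dm.Dataset.from_arrays(np.linspace(0.1, 5.0, 200))
        with pytest.raises(ValueError, match="GNG"):
            dm.fit("GNG", 1, data, dm.FitConfig())

    def test_nudge_pi_recovery(self):
        # truth: 10% uniform on [-5, 5] over a standard normal bulk
        rng = np.random.default_rng(2024)
        n = 20_000
        sig = rng.uniform(-5, 5, int(0.1 * n))
        y = np.concatenate([sig, rng.normal(0, 1, n - sig.size)])
        rng.shuffle(y)
        fr = dm.fit("NUDGE", 1, dm.Dataset.from_arrays(y),
                    dm.FitConfig(seed=1, n_restarts=2))
        assert fr.model.pi == pytest.approx(0.1, abs=0.03)
        assert fr.converged
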