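"""Densities, component decomposition, weights, and domain invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import diffmix as dm
from diffmix.core import component_weights

from conftest import random_model


def _nudge(pi=0.0, mu=0.0, s2=1.0, a=-5.0, b=5.0):
    return dm.MixtureModel(
        "NUDGE", pi, [dm.NormalComponent(mu, s2, 1.0)],
        dm.UniformComponent(a, b),
    )


class TestDensity:
    @pytest.mark.parametrize(
        "model, y, expected",
        [
            # pi=0 NUDGE reduces to the standard normal at its mode
            (_nudge(), 0.0, 1.0 / np.sqrt(2 * np.pi)),
            # pure uniform
            (
                dm.MixtureModel(
                    "iNUDGE", 1.0, [dm.NormalComponent(0, 1, 1.0)],
                    dm.UniformComponent(0, 2),
                ),
                1.0,
                0.5,
            ),
            # shifted exponential one scale unit past its offset
            (
                dm.MixtureModel(
                    "GNG", 1.0, [dm.NormalComponent(0, 1, 1.0)],
                    dm.ExponentialPair(1.0, 1.0, 1.0, 0.5, 0.5),
                ),
                -1.5,
                np.exp(-1.0),
            ),
        ],
    )
    def test_closed_form_values(self, model, y, expected):
        assert dm.density(model, [y])[0] == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonfinite_scores(self):
        with pytest.raises(ValueError):
            dm.density(_nudge(), [0.0, np.nan])

    def test_rejects_bad_gamma_sum(self):
        with pytest.raises(ValueError):
            dm.MixtureModel(
                "iNUDGE", 0.5,
                [dm.NormalComponent(0, 1, 0.6), dm.NormalComponent(1, 1, 0.6)],
                dm.UniformComponent(-1, 1),
            )

    @pytest.mark.parametrize("model_class", dm.core.MODEL_CLASSES)
    def test_integrates_to_one(self, model_class):
        # full 100-model sweep lives in the acceptance suite
        rng = np.random.default_rng(7)
        for _ in range(5):
            model = random_model(model_class, rng)
            total, _ = _integrate_density(model)
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_inudge_k1_equals_nudge(self):
        nudge = _nudge(pi=0.2, mu=0.3, s2=0.8)
        inudge = dm.MixtureModel(
            "iNUDGE", 0.2, [dm.NormalComponent(0.3, 0.8, 1.0)],
            dm.UniformComponent(-5, 5),
        )
        grid = np.linspace(-8, 8, 401)
        np.testing.assert_allclose(
            dm.density(nudge, grid), dm.density(inudge, grid), rtol=0, atol=0
        )


def _integrate_density(model):
    pts = [c.mu for c in model.normals]
    if isinstance(model.f1, dm.UniformComponent):
        pts += [model.f1.a, model.f1.b]
    else:
        pts += [-model.f1.xi1, model.f1.xi2]
    lo = min(pts) - 60
    hi = max(pts) + 60
    return quad(
        lambda v: dm.density(model, [v])[0], lo, hi,
        points=sorted(pts), limit=200,
    )


class TestComponentDensities:
    @pytest.mark.parametrize("model_class", dm.core.MODEL_CLASSES)
    def test_weighted_columns_reproduce_density(self, model_class, rng):
        model = random_model(model_class, rng)
        y = rng.normal(0, 3, 200)
        cols = dm.component_densities(model, y)
        assert cols.shape == (200, model.K + model.n_f1_parts)
        assert np.all(cols >= 0)
        np.testing.assert_allclose(
            cols @ component_weights(model), dm.density(model, y), atol=1e-12
        )

    def test_gng_gap_has_zero_exponential_density(self):
        model = dm.MixtureModel(
            "GNG", 0.5, [dm.NormalComponent(0, 1, 1.0)],
            dm.ExponentialPair(0.5, 1.0, 1.0, 0.4, 0.3),
        )
        cols = dm.component_densities(model, [0.0, -0.39, 0.29])
        np.testing.assert_array_equal(cols[:, 1:], 0.0)

    def test_uniform_column_is_constant_inside_support(self):
        model = dm.MixtureModel(
            "iNUDGE", 0.3,
            [dm.NormalComponent(0, 1, 0.5), dm.NormalComponent(1, 2, 0.5)],
            dm.UniformComponent(-2, 3),
        )
        cols = dm.component_densities(model, [-1.0, 0.0, 2.5])
        np.testing.assert_allclose(cols[:, 2], 1.0 / 5.0)


class TestWeights:
    @pytest.mark.parametrize(
        "u, expected",
        [(0.0, 1.0), (-1.345, 1.0), (-2.69, 0.5), (5.0, 1.0)],
    )
    def test_huber_lower_values(self, u, expected):
        assert dm.huber_lower_weight([u])[0] == pytest.approx(expected)

    def test_huber_continuous_at_cutoff(self):
        just_below = dm.huber_lower_weight([-1.345 - 1e-9])[0]
        assert just_below == pytest.approx(1.0, abs=1e-8)

    @given(st.floats(-50, 50))
    @settings(deadline=None)
    def test_huber_bounded_and_flat_above_cutoff(self, u):
        w = dm.huber_lower_weight([u])[0]
        assert 0.0 < w <= 1.0
        if u > -1.345:
            assert w == 1.0

    def test_huber_nonincreasing_below_cutoff(self):
        u = np.linspace(-30, -1.345, 500)
        w = dm.huber_lower_weight(u)
        assert np.all(np.diff(w) >= 0)  # less negative u -> larger weight

    @pytest.mark.parametrize(
        "u, expected", [(0.0, 1.0), (-1.345, 1.0), (-1.345 - 4.685, 0.0)]
    )
    def test_tukey_lower_values(self, u, expected):
        assert dm.tukey_lower_weight([u])[0] == pytest.approx(expected)

    def test_upper_and_two_tailed_mirror_lower(self):
        u = np.linspace(-4, 4, 101)
        np.testing.assert_allclose(
            dm.huber_upper_weight(u), dm.huber_lower_weight(-u)
        )
        np.testing.assert_allclose(
            dm.huber_two_tailed_weight(u),
            np.minimum(dm.huber_lower_weight(u), dm.huber_upper_weight(u)),
        )

    def test_invalid_tuning_constants(self):
        with pytest.raises(ValueError):
            dm.huber_lower_weight([0.0], c=0.0)
        with pytest.raises(ValueError):
            dm.tukey_lower_weight([0.0], taper=-1.0)


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        z = dm.standardize_intensity([1.0, 2.0, 3.0])
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self, rng):
        z = dm.standardize_intensity(rng.normal(3, 2, 50))
        np.testing.assert_allclose(
            dm.standardize_intensity(z), z, atol=1e-12
        )

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            dm.standardize_intensity([5.0, 5.0, 5.0])


class TestEstimateXi:
    def test_examples(self):
        assert dm.estimate_xi([-2, -0.5, 0.3, 1]) == (0.5, 0.3)
        assert dm.estimate_xi([-1, 1]) == (1.0, 1.0)

    def test_one_sided_data_rejected(self):
        with pytest.raises(ValueError, match="GNG"):
            dm.estimate_xi([0.1, 0.2])


class TestDataset:
    def test_defaults_unit_weights(self):
        d = dm.Dataset.from_arrays([0.0, 1.0, 2.0])
        np.testing.assert_array_equal(d.w, 1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"y": [np.inf, 0.0]},
            {"y": [0.0, 1.0], "w": [0.5, 1.5]},
            {"y": [0.0, 1.0], "u": [1.0]},
            {"y": [0.0]},
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            dm.Dataset.from_arrays(**kwargs)


class TestCdf:
    @pytest.mark.parametrize("model_class", dm.core.MODEL_CLASSES)
    def test_limits_and_monotonicity(self, model_class, rng):
        model = random_model(model_class, rng)
        grid = np.linspace(-60, 60, 2001)
        c = dm.cdf(model, grid)
        assert c[0] == pytest.approx(0.0, abs=1e-6)
        assert c[-1] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(c) >= -1e-12)

    def test_matches_quadrature_of_density(self, rng):
        model = random_model("GNG", rng)
        for x in (-2.0, 0.0, 1.5):
            val, _ = quad(
                lambda v: dm.density(model, [v])[0], -80, x,
                points=sorted([-model.f1.xi1, model.f1.xi2] +
                              [c.mu for c in model.normals]),
                limit=200,
            )
            assert dm.cdf(model, [x])[0] == pytest.approx(val, abs=1e-6)
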