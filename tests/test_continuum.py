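"""Phase-space line models: projection, R^2, AIC, Akaike weights."""

import numpy as np
import pytest

from gaitspace.continuum import (
    TROT_HALFBOUND,
    TROT_PACE,
    LineModel,
    PhaseContinuum,
    aic_weights,
    fit_continuum,
    grand_circular_mean,
    line_aic,
    line_r_squared,
    project_phases,
    project_step,
)
from gaitspace.gaits import mirror_point

TWO_PI = 2 * np.pi


def embed(model, lams, mirror=False):
    """Place points exactly on the line (cycles), optionally mirrored."""
    pts = (np.asarray(model.psi_a) + np.outer(np.asarray(lams), model.u_hat) / TWO_PI) % 1
    if mirror:
        pts = np.array([mirror_point(p) for p in pts])
    return pts


class TestLineModel:
    def test_endpoints_must_differ(self):
        with pytest.raises(ValueError):
            LineModel((0.5, 0.5, 0.0), (0.5, 0.5, 0.0))

    def test_unit_direction(self):
        assert np.linalg.norm(TROT_HALFBOUND.u_hat) == pytest.approx(1.0)
        assert TROT_HALFBOUND.length == pytest.approx(
            TWO_PI * np.sqrt(0.45**2 + 0.13**2 + 0.62**2)
        )


class TestProjection:
    @pytest.mark.parametrize("model", [TROT_HALFBOUND, TROT_PACE])
    def test_endpoints(self, model):
        lam, res, _ = project_step(model.psi_a, model)
        assert lam == pytest.approx(0.0, abs=1e-9)
        assert res == pytest.approx(0.0, abs=1e-9)
        lam, res, _ = project_step(model.psi_b, model)
        assert lam == pytest.approx(model.length)
        assert res == pytest.approx(0.0, abs=1e-9)

    def test_halfbound_endpoint_value(self):
        lam, _, _ = project_step(TROT_HALFBOUND.psi_b, TROT_HALFBOUND)
        assert lam == pytest.approx(4.882, abs=1e-3)

    def test_lambda_clamped_to_two_pi(self, rng):
        phis = rng.uniform(0, 1, (200, 3))
        for model in (TROT_HALFBOUND, TROT_PACE):
            lam, _, _ = project_phases(phis, model)
            assert np.all(np.abs(lam) <= TWO_PI + 1e-12)

    @pytest.mark.parametrize("model", [TROT_HALFBOUND, TROT_PACE])
    def test_matches_dense_grid_search(self, model, rng):
        """The analytic projection equals a brute-force grid minimization."""
        line = LineModel(model.psi_a, model.psi_b, use_mirror=False)
        grid = np.concatenate([np.arange(-TWO_PI, TWO_PI, 1e-3), [TWO_PI]])
        pts = line.psi_a_rad[None, :] + grid[:, None] * line.u_hat[None, :]
        for _ in range(150):
            phi = rng.uniform(0, 1, 3)
            lam, res, _ = project_step(phi, line)
            diff = TWO_PI * phi[None, :] - pts
            diff -= TWO_PI * np.floor(diff / TWO_PI + 0.5)
            d = np.sqrt((diff**2).sum(axis=1))
            assert res <= d.min() + 1e-6

    def test_mirrored_point_has_equal_lambda_on_mirror_branch(self, rng):
        lams = rng.uniform(0, TROT_HALFBOUND.length, 50)
        noise = rng.normal(0, 0.05, (50, 3))
        pts = (embed(TROT_HALFBOUND, lams) + noise / TWO_PI) % 1
        mirrored = np.array([mirror_point(p) for p in pts])
        lam_p, res_p, br_p = project_phases(pts, TROT_HALFBOUND)
        lam_m, res_m, br_m = project_phases(mirrored, TROT_HALFBOUND)
        assert np.allclose(lam_p, lam_m, atol=1e-9)
        assert np.allclose(res_p, res_m, atol=1e-9)
        assert np.all(br_p == "primary")
        assert np.all(br_m == "mirror")


class TestGrandCircularMean:
    def test_identical_points(self):
        mu = grand_circular_mean([(0.2, 0.6, 0.9)] * 4)
        assert mu == pytest.approx((0.2, 0.6, 0.9))

    def test_mean_across_the_wrap(self):
        mu = grand_circular_mean([(0.1, 0.3, 0.3), (0.9, 0.3, 0.3)])
        assert min(mu[0], 1 - mu[0]) == pytest.approx(0.0, abs=1e-9)

    def test_antipodal_pair_is_undefined(self):
        with pytest.raises(ValueError, match="resultant"):
            grand_circular_mean([(0.0, 0.3, 0.3), (0.5, 0.3, 0.3)])


class TestRSquared:
    def test_points_on_line_give_one(self, rng):
        pts = embed(TROT_HALFBOUND, rng.uniform(0, TROT_HALFBOUND.length, 100))
        r2, _ = line_r_squared(pts, TROT_HALFBOUND)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_decreases_with_orthogonal_residual(self, rng):
        u = TROT_HALFBOUND.u_hat
        w = np.cross(u, [0.0, 0.0, 1.0])
        w /= np.linalg.norm(w)
        lams = rng.uniform(0, TROT_HALFBOUND.length, 200)
        r2s = []
        for r in (0.0, 0.2, 0.4, 0.6):
            pts = (
                np.asarray(TROT_HALFBOUND.psi_a)
                + (np.outer(lams, u) + r * w) / TWO_PI
            ) % 1
            r2s.append(line_r_squared(pts, TROT_HALFBOUND)[0])
        assert all(a > b for a, b in zip(r2s, r2s[1:]))

    def test_random_points_fit_worse_than_on_line_points(self, rng):
        on_line = embed(TROT_HALFBOUND, rng.uniform(0, TROT_HALFBOUND.length, 200))
        random_pts = rng.uniform(0, 1, (200, 3))
        assert (
            line_r_squared(random_pts, TROT_HALFBOUND)[0]
            < line_r_squared(on_line, TROT_HALFBOUND)[0]
        )

    def test_invariant_under_permutation(self, rng):
        pts = rng.uniform(0, 1, (80, 3))
        perm = rng.permutation(80)
        a, _ = line_r_squared(pts, TROT_PACE)
        b, _ = line_r_squared(pts[perm], TROT_PACE)
        assert a == pytest.approx(b)

    def test_single_cluster_is_degenerate(self):
        pts = np.tile(np.asarray(TROT_HALFBOUND.psi_a), (10, 1))
        with pytest.raises(ValueError):
            fit_continuum(pts, models=(TROT_HALFBOUND,))

    def test_per_animal_values(self, rng):
        pts = embed(TROT_HALFBOUND, rng.uniform(0, TROT_HALFBOUND.length, 60))
        animals = ["a"] * 30 + ["b"] * 30
        _, per_animal = line_r_squared(pts, TROT_HALFBOUND, animal_ids=animals)
        assert set(per_animal) == {"a", "b"}
        for v in per_animal.values():
            assert v == pytest.approx(1.0, abs=1e-9)


class TestAic:
    def test_equal_residuals_equal_aic(self, rng):
        pts = rng.uniform(0, 1, (10, 3))
        res = np.full(10, 0.7)
        assert line_aic(pts, TROT_PACE, residuals=res) == line_aic(
            pts, TROT_HALFBOUND, residuals=res
        )

    def test_unit_mean_residual_gives_zero(self):
        pts = np.zeros((10, 3))
        assert line_aic(pts, TROT_PACE, residuals=np.ones(10)) == 0.0

    def test_common_scaling_shifts_by_n_log_c(self, rng):
        res = rng.uniform(0.1, 1.0, 25)
        pts = np.zeros((25, 3))
        base = line_aic(pts, TROT_PACE, residuals=res)
        scaled = line_aic(pts, TROT_PACE, residuals=3.0 * res)
        assert scaled - base == pytest.approx(25 * np.log(3.0))

    def test_zero_residuals_warn_and_return_minus_inf(self):
        with pytest.warns(RuntimeWarning):
            aic = line_aic(np.zeros((5, 3)), TROT_PACE, residuals=np.zeros(5))
        assert aic == -np.inf


class TestAicWeights:
    def test_equal_aics(self):
        assert aic_weights([10.0, 10.0]) == pytest.approx([0.5, 0.5])

    def test_delta_two(self):
        w = aic_weights([0.0, 2.0])
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    def test_sum_to_one(self, rng):
        for _ in range(20):
            w = aic_weights(rng.uniform(-50, 50, 4))
            assert w.sum() == pytest.approx(1.0)
            assert np.all(w >= 0)


class TestFit:
    def test_on_line_mirror_split_recovers_branches(self, rng):
        lams = rng.uniform(0, TROT_HALFBOUND.length, 400)
        pts = embed(TROT_HALFBOUND, lams)
        pts[200:] = embed(TROT_HALFBOUND, lams[200:], mirror=True)
        results = fit_continuum(pts, models=(TROT_HALFBOUND,))
        fit = results.fits["trot-halfbound"]
        assert fit.r2_overall == pytest.approx(1.0, abs=1e-9)
        assert np.all(fit.branch[:200] == "primary")
        assert np.all(fit.branch[200:] == "mirror")
        assert np.allclose(fit.lambdas, lams, atol=1e-9)

    def test_lambda_recovery_under_isotropic_noise(self, rng):
        """Steps at known positions along the line, isotropic circular noise
        of total concentration kappa=200: mean |lambda error| < 0.05 rad."""
        kappa = 200.0
        sigma = 1.0 / np.sqrt(3.0 * kappa)  # per component
        lams = rng.uniform(0, TROT_HALFBOUND.length, 1000)
        noise = rng.normal(0.0, sigma, (1000, 3))
        pts = (embed(TROT_HALFBOUND, lams) + noise / TWO_PI) % 1
        lam_hat, _, _ = project_phases(pts, TROT_HALFBOUND)
        assert np.mean(np.abs(lam_hat - lams)) < 0.05

    def test_trot_pace_data_selects_trot_pace_model(self, rng):
        h = 0.5 + np.cumsum(rng.normal(0, 0.05, 300))
        pts = np.stack([np.full(300, 0.5), h % 1, (h + 0.5) % 1], axis=1)
        results = fit_continuum(pts, models=(TROT_HALFBOUND, TROT_PACE))
        assert results.aic_weights["trot-pace"] > 0.999
        assert (
            results.fits["trot-pace"].r2_overall
            > results.fits["trot-halfbound"].r2_overall
        )

    def test_summary_lists_all_models(self, rng):
        pts = rng.uniform(0, 1, (50, 3))
        results = PhaseContinuum(pts, animal_ids=["a"] * 25 + ["b"] * 25).fit()
        text = results.summary()
        assert "trot-halfbound" in text and "trot-pace" in text
        frame = results.summary_frame()
        assert frame.loc["trot-pace", "n"] == 50
        assert frame["aic_weight"].sum() == pytest.approx(1.0)
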