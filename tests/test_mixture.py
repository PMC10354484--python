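"""EM mixture fitting: fixed points, degeneracy, parameter recovery,
posterior probabilities, and independent oracles."""

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from whalepreg.mixture import (
    ComponentLabels,
    MixtureFit,
    TwoComponentNormalMixture,
    em_fit,
    label_components,
    posterior_pregnancy,
)

WELL_SEPARATED = np.array([-0.1, 0.0, 0.1, 4.9, 5.0, 5.1])


class TestEmFit:
    def test_well_separated_clusters_recover_sample_moments(self):
        fit = em_fit(WELL_SEPARATED, rng=0)
        assert fit.converged
        means = np.sort(fit.means.ravel())
        assert means == pytest.approx([0.0, 5.0], abs=1e-6)
        assert fit.weights == pytest.approx([0.5, 0.5], abs=1e-6)
        # EM fixed point: component variances equal per-cluster moments
        assert np.sort(fit.covariances.ravel()) == pytest.approx(
            [0.02 / 3, 0.02 / 3], rel=1e-4
        )

    def test_identical_data_flagged_degenerate(self):
        fit = em_fit(np.full(10, 3.3), rng=0)
        assert not fit.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            em_fit(np.array([1.0, 2.0, 3.0]))

    def test_loglik_monotone_every_iteration(self):
        rng = np.random.default_rng(5)
        datasets = [
            WELL_SEPARATED,
            np.concatenate([rng.normal(0, 1, 40), rng.normal(2, 1.5, 60)]),
            rng.normal(size=30),  # single-component data: EM still monotone
            np.column_stack(
                [
                    np.concatenate([rng.normal(4.1, 0.8, 50), rng.normal(4.6, 1.2, 50)]),
                    np.concatenate([rng.normal(0.15, 0.01, 50), rng.normal(0.18, 0.01, 50)]),
                ]
            ),
        ]
        for data in datasets:
            fit = em_fit(data, rng=1)
            diffs = np.diff(fit.loglik_path)
            assert (diffs >= -1e-7 * np.abs(fit.loglik_path[:-1])).all()

    def test_parameter_recovery_univariate(self):
        rng = np.random.default_rng(7)
        n = 500
        z = rng.uniform(size=n) < 0.4
        x = np.where(z, rng.normal(0.178, 0.01, n), rng.normal(0.15, 0.01, n))
        fit = em_fit(x, rng=3)
        labels = label_components(fit)
        mu_hi = fit.means[labels.high, 0]
        mu_lo = fit.means[labels.low, 0]
        # 3 x the sampling sd of the ML component means at these settings,
        # calibrated by simulation with an independent mixture implementation
        # (overlap inflates it well above sd / sqrt(n * weight))
        assert abs(mu_hi - 0.178) < 3 * 0.0018
        assert abs(mu_lo - 0.150) < 3 * 0.0013

    def test_parameter_recovery_bivariate(self):
        rng = np.random.default_rng(11)
        n = 500
        z = rng.uniform(size=n) < 0.5
        fp4m = np.where(z, rng.normal(4.6, 1.15, n), rng.normal(4.1, 0.77, n))
        w50 = np.where(z, rng.normal(0.178, 0.01, n), rng.normal(0.15, 0.01, n))
        fit = em_fit(np.column_stack([fp4m, w50]), rng=3)
        labels = label_components(fit)
        assert labels.valid
        hi = fit.means[labels.high]
        # W50 separates cleanly, so the W50 coordinate identifies components;
        # 3 x simulation-calibrated sampling sd of that coordinate's ML mean
        assert abs(hi[1] - 0.178) < 3 * 0.005

    def test_matches_sklearn_reference(self):
        """Independent cross-check against sklearn's GaussianMixture."""
        rng = np.random.default_rng(13)
        n = 400
        z = rng.uniform(size=n) < 0.45
        x = np.where(z, rng.normal(3.0, 0.8, n), rng.normal(0.0, 1.0, n))[:, None]
        ours = em_fit(x, rng=1)
        ref = GaussianMixture(
            n_components=2, covariance_type="full", tol=1e-8, max_iter=2000,
            n_init=10, random_state=0, reg_covar=1e-10,
        ).fit(x)
        assert ours.loglik == pytest.approx(ref.score(x) * n, rel=1e-5)
        assert np.sort(ours.means.ravel()) == pytest.approx(
            np.sort(ref.means_.ravel()), abs=1e-3
        )
        assert np.sort(ours.weights) == pytest.approx(np.sort(ref.weights_), abs=1e-3)

    def test_beats_random_search_oracle_on_tiny_data(self):
        """On n <= 8 points the converged EM log-likelihood dominates a
        brute-force lower bound from 1000 random parameter draws."""
        rng = np.random.default_rng(17)
        for data in (
            np.array([0.1, 0.2, 1.9, 2.0, 2.1, 5.0]),
            rng.normal(size=8),
        ):
            fit = em_fit(data, rng=2)
            lo, hi = data.min(), data.max()
            span = hi - lo
            best = -np.inf
            for _ in range(1000):
                w = rng.uniform(0.05, 0.95)
                mu = rng.uniform(lo, hi, 2)
                sd = rng.uniform(0.05 * span, span, 2)
                dens = w * norm.pdf(data, mu[0], sd[0]) + (1 - w) * norm.pdf(
                    data, mu[1], sd[1]
                )
                best = max(best, np.log(dens).sum())
            assert fit.loglik >= best


class TestLabels:
    def test_dominating_component(self):
        fit = _fit_with(means=[[0.0, 0.0], [5.0, 5.0]])
        labels = label_components(fit)
        assert labels.high == 1 and labels.valid

    def test_no_dominating_component_invalid(self):
        fit = _fit_with(means=[[0.0, 5.0], [5.0, 0.0]])
        assert not label_components(fit).valid

    def test_univariate_higher_mean(self):
        fit = _fit_with(means=[[3.0], [4.0]])
        labels = label_components(fit)
        assert labels.high == 1 and labels.low == 0 and labels.valid


def _fit_with(means, weights=(0.5, 0.5), covs=None):
    means = np.asarray(means, dtype=float)
    dim = means.shape[1]
    if covs is None:
        covs = np.stack([np.eye(dim), np.eye(dim)])
    return MixtureFit(
        dim=dim,
        weights=np.asarray(weights, dtype=float),
        means=means,
        covariances=np.asarray(covs, dtype=float),
        loglik=0.0,
        n_iter=1,
        converged=True,
    )


class TestPosteriorPregnancy:
    def test_midpoint_symmetry_both_modes(self):
        fit = _fit_with(means=[[0.0], [5.0]])
        labels = label_components(fit)
        for mode in ("responsibility", "literal"):
            assert posterior_pregnancy(fit, labels, 2.5, mode) == pytest.approx(0.5)

    def test_limit_at_high_mean(self):
        fit = _fit_with(means=[[0.0], [50.0]])
        labels = label_components(fit)
        assert posterior_pregnancy(fit, labels, 50.0) == pytest.approx(1.0, abs=1e-12)

    def test_literal_closed_form(self):
        # means (0, 5), unit sds, x = 2: log-density gap is 5 * (2.5 - 2)
        fit = _fit_with(means=[[0.0], [5.0]])
        labels = label_components(fit)
        expected = 1.0 / (1.0 + np.exp(5.0 * 0.5))
        assert posterior_pregnancy(fit, labels, 2.0, "literal") == pytest.approx(expected)
        assert expected == pytest.approx(0.0759, abs=1e-4)

    def test_far_tail_never_nan(self):
        fit = _fit_with(means=[[0.0], [5.0]])
        labels = label_components(fit)
        p = posterior_pregnancy(fit, labels, np.array([-1e3, 1e3]))
        assert np.isfinite(p).all()
        assert p[0] == 0.0 and p[1] == 1.0

    def test_label_swap_invariance_bit_exact(self):
        fit = em_fit(WELL_SEPARATED, rng=0)
        labels = label_components(fit)
        swapped = MixtureFit(
            dim=fit.dim,
            weights=fit.weights[::-1].copy(),
            means=fit.means[::-1].copy(),
            covariances=fit.covariances[::-1].copy(),
            loglik=fit.loglik,
            n_iter=fit.n_iter,
            converged=fit.converged,
        )
        labels_s = label_components(swapped)
        x = np.linspace(-1, 6, 23)
        p1 = posterior_pregnancy(fit, labels, x)
        p2 = posterior_pregnancy(swapped, labels_s, x)
        assert (p1 == p2).all()

    def test_monotone_with_equal_covariances(self):
        fit = _fit_with(means=[[0.0], [3.0]])  # shared unit variances
        labels = label_components(fit)
        x = np.linspace(-5, 8, 200)
        p = posterior_pregnancy(fit, labels, x)
        assert (np.diff(p) >= -1e-15).all()

    def test_invalid_labels_rejected(self):
        fit = _fit_with(means=[[0.0, 5.0], [5.0, 0.0]])
        with pytest.raises(ValueError):
            posterior_pregnancy(fit, ComponentLabels(1, 0, False), [1.0, 1.0])


class TestEstimatorInterface:
    def test_sklearn_protocol(self):
        est = TwoComponentNormalMixture(random_state=0)
        params = est.get_params()
        assert "tol" in params and "weighting_mode" in params
        est.set_params(max_iter=500)
        assert est.max_iter == 500

    def test_fit_predict_shapes(self):
        est = TwoComponentNormalMixture(random_state=0).fit(WELL_SEPARATED)
        proba = est.predict_proba(np.array([0.0, 5.0]))
        assert proba.shape == (2, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert est.predict(np.array([0.0, 5.0])).tolist() == [0, 1]

    def test_fit_is_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(60, 2))
        a = TwoComponentNormalMixture(random_state=9).fit(x)
        b = TwoComponentNormalMixture(random_state=9).fit(x)
        assert a.loglik_ == b.loglik_
        assert (a.means_ == b.means_).all()

    def test_serialization_round_trip(self):
        import json

        fit = em_fit(WELL_SEPARATED, rng=0)
        blob = json.loads(fit.to_json())
        assert blob["converged"] is True
        assert np.asarray(blob["means"]).shape == (2, 1)
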