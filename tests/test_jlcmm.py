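"""Latent-class joint model: mixture likelihood, EM fit, hazard-ratio
summaries and the delete-5 jackknife."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from dietsurv.hazard import HazardSpec
from dietsurv.jlcmm import (JLCMM_HAZARD, JlcmmConfig, JlcmmData,
                            JlcmmParams, fit_jlcmm, jackknife_d5,
                            jlcmm_loglik, overall_hr_proportional,
                            piecewise_hr, select_num_classes)
from dietsurv.lmm import LmmParams, fit_lmm, lmm_loglik
from dietsurv.splines import SplineSpec, bspline_basis


@pytest.fixture(scope="module")
def spec():
    return SplineSpec()


def _toy_data(spec, n=4, seed=8):
    rng = np.random.default_rng(seed)
    ages = [0.5, 2.0, 5.0]
    rows = []
    for s in range(1, n + 1):
        for a in ages:
            rows.append((s, a, float(rng.normal(5 * a, 2.0)), 3.0))
    long = pd.DataFrame(rows, columns=["subject", "age_years",
                                       "food_g_day", "energy_mj_day"])
    T = np.array([3.0, 15.0, 8.8, 15.0])[:n]
    ev = np.array([1, 0, 1, 0])[:n]
    eps = pd.DataFrame({
        "subject": np.arange(1, n + 1), "last_negative_age": T,
        "first_positive_age": np.where(ev, T, np.nan), "event": ev,
        "censor_age": np.where(ev, np.nan, T),
    })
    return long, eps


def _toy_params(spec, G=2, identical=False):
    p = spec.n_coef
    rng = np.random.default_rng(4)
    beta1 = np.linspace(0, 20, p)
    beta2 = beta1 if identical else beta1 + rng.normal(0, 3, p)
    lam = np.array([0.4, 0.0])[:G]
    if G == 1:
        lam = np.zeros(1)
        betas = beta1[None, :]
        xi = np.log([[0.01, 0.012, 0.008, 0.004]])
    else:
        betas = np.vstack([beta1, beta2])
        xi2 = ([0.01, 0.012, 0.008, 0.004] if identical
               else [0.007, 0.009, 0.005, 0.003])
        xi = np.log([[0.01, 0.012, 0.008, 0.004], xi2])
    return JlcmmParams(lam, betas, np.log(np.linspace(1, 4, p)),
                       float(np.log(4.0)), np.zeros(0), xi)


class TestLoglik:
    def test_hand_computed_mixture_oracle(self, spec):
        """4-subject toy: the mixture log-likelihood equals an explicit
        sum over classes of Gaussian-marginal times piecewise-exponential
        terms."""
        long, eps = _toy_data(spec)
        params = _toy_params(spec)
        data = JlcmmData.build(long, eps, None, spec, JLCMM_HAZARD)
        ours = jlcmm_loglik(params, data)
        ref = 0.0
        pi = params.pi
        for i, s in enumerate(range(1, 5)):
            g = long[long.subject == s]
            Z = bspline_basis(g.age_years.to_numpy(), spec)
            cov = Z @ np.diag(params.d) @ Z.T + params.sigma2 * np.eye(len(g))
            T = data.T[i]
            dlt = data.delta[i]
            terms = []
            for k in range(2):
                llong = multivariate_normal.logpdf(
                    g.food_g_day.to_numpy(), Z @ params.beta[k], cov
                )
                h = np.exp(params.log_heights[k])
                H = JLCMM_HAZARD.exposure(np.array([T]))[0] @ h
                seg = int(JLCMM_HAZARD.segment_of(T))
                lsurv = dlt * params.log_heights[k][seg] - H
                terms.append(np.log(pi[k]) + llong + lsurv)
            ref += np.logaddexp(*terms)
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_single_class_factorizes(self, spec):
        long, eps = _toy_data(spec)
        params = _toy_params(spec, G=1)
        data = JlcmmData.build(long, eps, None, spec, JLCMM_HAZARD)
        ll = jlcmm_loglik(params, data)
        lmm_p = LmmParams(params.beta[0], params.log_d, params.log_sigma2)
        ll_long = lmm_loglik(lmm_p, data.long)
        h = np.exp(params.log_heights[0])
        ll_surv = float(
            (data.delta * params.log_heights[0][data.segT]).sum()
            - (data.expo @ h).sum()
        )
        assert ll == pytest.approx(ll_long + ll_surv, abs=1e-9)

    def test_identical_classes_degenerate_to_one(self, spec):
        long, eps = _toy_data(spec)
        p2 = _toy_params(spec, G=2, identical=True)
        p1 = JlcmmParams(np.zeros(1), p2.beta[:1], p2.log_d,
                         p2.log_sigma2, p2.gamma, p2.log_heights[:1])
        data = JlcmmData.build(long, eps, None, spec, JLCMM_HAZARD)
        assert jlcmm_loglik(p2, data) == pytest.approx(
            jlcmm_loglik(p1, data), abs=1e-9
        )

    def test_label_switching_invariance(self, spec):
        long, eps = _toy_data(spec)
        params = _toy_params(spec)
        data = JlcmmData.build(long, eps, None, spec, JLCMM_HAZARD)
        swapped = params.reordered(np.array([1, 0]))
        assert jlcmm_loglik(params, data) == pytest.approx(
            jlcmm_loglik(swapped, data), abs=1e-9
        )


class TestFit:
    def test_two_class_recovery_and_posteriors(self, lc_cohort):
        coh, truth = lc_cohort
        fit = fit_jlcmm(coh.long, coh.endpoints, coh.baseline, truth.spec,
                        G=2, config=JlcmmConfig(starts=2, seed=3,
                                                compute_se=False))
        np.testing.assert_allclose(fit.posterior.sum(axis=1), 1.0,
                                   atol=1e-12)
        acc = (fit.modal == coh.labels).mean()
        assert max(acc, 1 - acc) >= 0.9
        # classes reported in descending size order
        assert fit.class_sizes[0] >= fit.class_sizes[1]
        assert np.all(np.diff(fit.em_trace) >= -1e-8)

    def test_g1_reduces_to_mixed_model(self, small_cohort, spec):
        fit = fit_jlcmm(small_cohort.long, small_cohort.endpoints, None,
                        spec, G=1,
                        hazard=HazardSpec(knots=(1.99, 3.99),
                                          followup_max=6.0),
                        config=JlcmmConfig(compute_se=False, polish=False))
        lmm_fit = fit_lmm(small_cohort.long, spec)
        data = JlcmmData.build(small_cohort.long, small_cohort.endpoints,
                               None, spec,
                               HazardSpec(knots=(1.99, 3.99),
                                          followup_max=6.0))
        h = np.exp(fit.params.log_heights[0])
        ll_surv = float(
            (data.delta * fit.params.log_heights[0][data.segT]).sum()
            - (data.expo @ h).sum()
        )
        assert fit.loglik == pytest.approx(lmm_fit.loglik + ll_surv,
                                           abs=1e-4)

    def test_bic_prefers_single_class_for_homogeneous_data(self, spec):
        from dietsurv.simulate import (CohortConfig, default_jm_truth,
                                       simulate_cohort)

        truth = default_jm_truth(hr_per_10g=1.0, adjusted=False)
        wins = 0
        reps = 3
        for rep in range(reps):
            cfg = CohortConfig(n_subjects=250, followup_max=6.0,
                               seed=7000 + rep)
            coh = simulate_cohort(cfg, truth)
            hz6 = HazardSpec(knots=(1.99, 3.99), followup_max=6.0)
            cfg_fit = JlcmmConfig(starts=2, seed=rep, compute_se=False,
                                  polish=False)
            f1 = fit_jlcmm(coh.long, coh.endpoints, None, spec, G=1,
                           hazard=hz6, config=cfg_fit)
            f2 = fit_jlcmm(coh.long, coh.endpoints, None, spec, G=2,
                           hazard=hz6, config=cfg_fit)
            wins += f1.bic < f2.bic
        assert wins >= reps - 1

    def test_invalid_G_rejected(self, small_cohort, spec):
        with pytest.raises(ValueError):
            fit_jlcmm(small_cohort.long, small_cohort.endpoints, None,
                      spec, G=0)


class TestSelection:
    @staticmethod
    def _fake_fit(G, bic, n=100):
        post = np.full((n, G), 1.0 / G)
        post[:, 0] = 0.9 if G > 1 else 1.0
        post /= post.sum(axis=1, keepdims=True)
        modal = np.zeros(n, dtype=int)
        modal[: n // (G + 1) * (G - 1)] = np.arange(
            n // (G + 1) * (G - 1)
        ) % G
        return dataclasses.replace(
            _EMPTY_FIT, params=_toy_params(SplineSpec(), G=min(G, 2)),
            loglik=-bic / 2, bic=bic, posterior=post, modal=modal,
            n_subjects=n,
        )

    def test_elbow_and_tie_break(self):
        fits = [self._fake_fit(G, bic)
                for G, bic in [(1, 500.0), (2, 450.0), (3, 470.0)]]
        for f, G in zip(fits, (1, 2, 3)):
            f.params = dataclasses.replace(
                f.params,
                lam=np.zeros(G), beta=np.zeros((G, 6)),
                log_heights=np.zeros((G, 4)),
            )
        chosen, table = select_num_classes(fits)
        assert chosen == 2
        # exact tie: fewer classes preferred
        fits[2].bic = 450.0
        chosen, _ = select_num_classes(fits)
        assert chosen == 2
        fits[0].bic = 450.0
        chosen, _ = select_num_classes(fits)
        assert chosen == 1


_EMPTY_FIT = None


def setup_module(module):
    global _EMPTY_FIT
    from dietsurv.jlcmm import JlcmmFit

    module._EMPTY_FIT = JlcmmFit(
        params=None, loglik=0.0, bic=0.0, converged=True,
        posterior=np.ones((1, 1)), modal=np.zeros(1, dtype=int),
        subjects=np.array([1]), n_subjects=1, spec=SplineSpec(),
        hazard=JLCMM_HAZARD, w_names=[],
    )


@pytest.fixture(scope="module")
def se_fit(lc_cohort):
    coh, truth = lc_cohort
    return fit_jlcmm(coh.long, coh.endpoints, None, truth.spec, G=2,
                     config=JlcmmConfig(starts=2, seed=3,
                                        compute_se=True)), coh, truth


class TestHazardRatios:
    def test_piecewise_hr_recovers_ratio(self, se_fit):
        fit, coh, truth = se_fit
        tab = piecewise_hr(fit)
        assert len(tab) == 4
        # truth has class-2/class-1 height ratio 0.68 in every interval;
        # at this sample size each interval is noisy, so check that most
        # intervals cover the truth
        covered = ((tab["lo"] <= 0.68) & (0.68 <= tab["hi"])).sum()
        assert covered >= 3

    def test_identical_hazards_give_unit_hr(self, se_fit):
        fit, _, _ = se_fit
        eq = dataclasses.replace(
            fit, params=dataclasses.replace(
                fit.params,
                log_heights=np.vstack([fit.params.log_heights[0]] * 2),
            )
        )
        tab = piecewise_hr(eq)
        np.testing.assert_allclose(tab["hr"], 1.0, atol=1e-12)
        assert ((tab["lo"] <= 1.0) & (1.0 <= tab["hi"])).all()

    def test_delta_se_close_to_parametric_draws(self, se_fit, rng):
        """Delta-method SE of each log piecewise HR versus the SD of HRs
        induced by 200 normal parameter draws from the fit covariance."""
        fit, _, _ = se_fit
        tab = piecewise_hr(fit)
        i1 = [fit.param_names.index(f"xi1_{j}") for j in range(4)]
        i2 = [fit.param_names.index(f"xi2_{j}") for j in range(4)]
        draws = rng.multivariate_normal(
            np.zeros(len(fit.param_names)), fit.cov, size=200,
            method="svd",
        )
        compared = 0
        for j in range(4):
            delta_se = (np.log(tab["hi"][j]) - np.log(tab["lo"][j])) / (
                2 * 1.96
            )
            if not np.isfinite(delta_se) or delta_se > 3:
                # hazard segment with almost no events in one class: the
                # log-HR there is unidentified and its SE unbounded
                continue
            mc = np.std(
                fit.params.log_heights[1, j] + draws[:, i2[j]]
                - fit.params.log_heights[0, j] - draws[:, i1[j]]
            )
            assert delta_se == pytest.approx(mc, rel=0.25)
            compared += 1
        assert compared >= 2

    def test_misaligned_interval_rejected(self, se_fit):
        fit, _, _ = se_fit
        with pytest.raises(ValueError, match="align"):
            piecewise_hr(fit, intervals=((0, 3), (3, 15)))

    def test_proportional_fit_nested_below_unconstrained(self, se_fit):
        fit, coh, truth = se_fit
        prop = overall_hr_proportional(
            coh.long, coh.endpoints, None, truth.spec,
            config=JlcmmConfig(starts=2, seed=3), init_fit=fit,
        )
        assert prop.loglik <= fit.loglik + 1e-6
        assert prop.lo <= prop.hr <= prop.hi


class TestJackknife:
    def test_sample_mean_matches_analytic_se(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=200)
        ids = np.arange(200)

        res = jackknife_d5(ids, lambda keep: x[keep].mean(), seed=5,
                           n_resamples=300)
        assert res["se"] == pytest.approx(x.std(ddof=1) / np.sqrt(200),
                                          rel=0.15)

    def test_constant_estimator_zero_se(self):
        res = jackknife_d5(np.arange(60), lambda keep: 3.14, seed=0,
                           n_resamples=50)
        assert res["se"] == pytest.approx(0.0, abs=1e-12)

    def test_reproducible_and_failure_counting(self):
        ids = np.arange(80)

        def flaky(keep):
            if keep[0] % 7 == 0:
                raise RuntimeError("no convergence")
            return float(keep.sum())

        a = jackknife_d5(ids, flaky, seed=2, n_resamples=40)
        b = jackknife_d5(ids, flaky, seed=2, n_resamples=40)
        assert a == b
        assert a["n_failed"] + a["n_resamples"] == 40
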