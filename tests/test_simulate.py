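"""Synthetic cohort generator: covariate frequencies, trajectory moments,
event-time distribution and visit censoring."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, kstwobign

from dietsurv.simulate import (CohortConfig, apply_visit_censoring,
                               default_antibody_visits, default_jm_truth,
                               default_jlcmm_truth, simulate_baseline,
                               simulate_cohort, simulate_event_times,
                               simulate_latent_class_cohort,
                               simulate_trajectories, write_cohort)
from dietsurv.splines import bspline_basis


class TestBaseline:
    def test_marginal_frequencies_goodness_of_fit(self):
        cfg = CohortConfig(n_subjects=100_000, seed=5)
        b = simulate_baseline(cfg)
        for col, probs in [
            ("sex", {"boy": 0.532, "girl": 0.468}),
            ("genetic_risk", {"high": 0.196, "moderate": 0.804}),
            ("familial_diabetes", {"yes": 0.059, "missing": 0.039,
                                   "no": 0.902}),
        ]:
            counts = b[col].value_counts()
            obs = [counts.get(k, 0) for k in probs]
            exp = [p * len(b) for p in probs.values()]
            assert chisquare(obs, exp).pvalue > 0.01

    def test_degenerate_probability(self):
        b = simulate_baseline(CohortConfig(n_subjects=50, sex_prob=1.0,
                                           seed=1))
        assert (b["sex"] == "boy").all()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            CohortConfig(sex_prob=1.4)

    def test_seed_reproducibility(self):
        a = simulate_baseline(CohortConfig(n_subjects=200, seed=9))
        b = simulate_baseline(CohortConfig(n_subjects=200, seed=9))
        pd.testing.assert_frame_equal(a, b)


class TestTrajectories:
    def test_noise_free_limit_lies_on_fixed_curve(self, rng):
        truth = default_jm_truth()
        truth.params.log_d = np.full(6, -300.0)
        truth.params.log_sigma2 = -300.0
        cfg = CohortConfig(n_subjects=20, seed=3, include_age5_prob=0.0)
        base = simulate_baseline(cfg, rng)
        long, _ = simulate_trajectories(base, truth, cfg, rng)
        B = bspline_basis(long["age_years"].to_numpy(), truth.spec)
        np.testing.assert_allclose(long["food_g_day"],
                                   B @ truth.params.beta, atol=1e-10)

    def test_no_consumption_at_first_record(self, rng):
        truth = default_jm_truth()
        cfg = CohortConfig(n_subjects=4000, seed=8)
        base = simulate_baseline(cfg, rng)
        long, _ = simulate_trajectories(base, truth, cfg, rng)
        first = long[long["age_years"] == 0.25]["food_g_day"]
        assert abs(first.mean()) < 2.0  # g/day, against a 35 g/day noise SD

    def test_moments_match_linear_mixed_model(self, rng):
        """Sample mean and variance of y at each scheduled age agree with
        B'beta and B'DB + sigma^2 within Monte-Carlo error."""
        truth = default_jm_truth()
        cfg = CohortConfig(n_subjects=2000, seed=11, include_age5_prob=0.0)
        base = simulate_baseline(cfg, rng)
        long, _ = simulate_trajectories(base, truth, cfg, rng)
        for age, g in long.groupby("age_years"):
            B = bspline_basis(np.array([age]), truth.spec)[0]
            mean = B @ truth.params.beta
            var = B @ np.diag(truth.params.d) @ B + truth.params.sigma2
            n = len(g)
            se_mean = np.sqrt(var / n)
            se_var = var * np.sqrt(2 / (n - 1))
            assert abs(g["food_g_day"].mean() - mean) < 3 * se_mean
            assert abs(g["food_g_day"].var() - var) < 3 * se_var

    def test_floor_at_zero_flag(self, rng):
        truth = default_jm_truth()
        cfg = CohortConfig(n_subjects=300, seed=3, floor_at_zero=True)
        base = simulate_baseline(cfg, rng)
        long, _ = simulate_trajectories(base, truth, cfg, rng)
        assert (long["food_g_day"] >= 0).all()
        assert long["floored"].any()


class TestEventTimes:
    def test_exponential_limit(self):
        """alpha=0, gamma=0, constant hazard lambda: event times are
        Exponential(lambda)."""
        lam = 0.3
        truth = default_jm_truth(adjusted=False)
        truth.params.alpha = 0.0
        truth.params.log_heights = np.log([lam, lam, lam])
        cfg = CohortConfig(n_subjects=30_000, seed=21, followup_max=6.0)
        rng = np.random.default_rng(2)
        base = simulate_baseline(cfg, rng)
        b = np.zeros((len(base), 6))
        T = simulate_event_times(base, truth, b, rng)
        fin = T[np.isfinite(T)]
        # censored mean of Exp(lam) on [0, 6]
        expect = 1 / lam - 6 * np.exp(-lam * 6) / (1 - np.exp(-lam * 6))
        assert fin.mean() == pytest.approx(expect, rel=0.02)
        assert (np.isfinite(T)).mean() == pytest.approx(
            1 - np.exp(-lam * 6), abs=0.01
        )

    def test_zero_hazard_gives_no_events(self):
        truth = default_jm_truth(adjusted=False)
        truth.params.log_heights = np.full(3, -700.0)
        cfg = CohortConfig(n_subjects=500, seed=4, followup_max=6.0)
        rng = np.random.default_rng(3)
        base = simulate_baseline(cfg, rng)
        T = simulate_event_times(base, truth, np.zeros((500, 6)), rng)
        assert np.isinf(T).all()

    def test_ks_against_independent_cdf_oracle(self):
        """alpha != 0, one fixed random-effect vector: the simulated event
        ages match the CDF computed independently via Gauss-Legendre
        cumulative hazards."""
        from dietsurv.jm import cumulative_hazard

        truth = default_jm_truth(adjusted=False)
        n = 8000
        cfg = CohortConfig(n_subjects=n, seed=33, followup_max=6.0)
        rng = np.random.default_rng(12)
        base = simulate_baseline(cfg, rng)
        b1 = np.array([0.5, -3.0, 10.0, -12.0, 25.0, 40.0])
        b = np.tile(b1, (n, 1))
        T = simulate_event_times(base, truth, b, rng)
        fin = np.sort(T[np.isfinite(T)])
        grid = np.linspace(1e-6, 6.0, 121)
        H = np.array([
            cumulative_hazard(t, np.zeros(0), b1, truth.params,
                              truth.spec, truth.hazard, gl_points=20)
            for t in grid
        ])
        F = 1 - np.exp(-H)
        F_cond = np.interp(fin, grid, F) / F[-1]
        emp = np.arange(1, len(fin) + 1) / len(fin)
        ks = np.max(np.abs(F_cond - emp))
        crit = kstwobign.ppf(0.99) / np.sqrt(len(fin))
        assert ks < crit


class TestVisitCensoring:
    def test_direct_interval_definition(self):
        visits = [np.array([1.0, 2.0, 3.0, 4.0])]
        out = apply_visit_censoring(np.array([3.2]), visits)
        row = out.iloc[0]
        assert (row["last_negative_age"], row["first_positive_age"]) == (
            3.0, 4.0
        )
        assert row["event"] == 1
        assert 0.5 * (3.0 + 4.0) == 3.5

    def test_no_event_censored_at_last_visit(self):
        out = apply_visit_censoring(np.array([np.inf]),
                                    [np.array([1.0, 14.9])])
        row = out.iloc[0]
        assert row["event"] == 0 and row["censor_age"] == 14.9

    def test_event_before_first_visit_flagged(self):
        out = apply_visit_censoring(np.array([0.1]),
                                    [np.array([0.25, 0.5])])
        row = out.iloc[0]
        assert row["last_negative_age"] == 0.0
        assert bool(row["event_before_first_visit"])

    def test_midpoints_inside_intervals(self, small_cohort):
        ev = small_cohort.endpoints.query("event == 1")
        mid = 0.5 * (ev["last_negative_age"] + ev["first_positive_age"])
        assert ((mid > ev["last_negative_age"])
                & (mid <= ev["first_positive_age"])).all()

    def test_invalid_visits_rejected(self):
        with pytest.raises(ValueError):
            apply_visit_censoring(np.array([1.0]), [np.array([2.0, 1.0])])


class TestCohortAssembly:
    def test_records_never_pass_detection_or_dropout(self, small_cohort):
        eps = small_cohort.endpoints.set_index("subject")
        for s, g in small_cohort.long.groupby("subject"):
            r = eps.loc[s]
            cutoff = (r["first_positive_age"] if r["event"] == 1
                      else r["censor_age"])
            assert (g["age_years"] <= cutoff + 1e-12).all()

    def test_full_cohort_incidence_and_retention(self):
        coh = simulate_latent_class_cohort(
            CohortConfig(n_subjects=5545, seed=20190523)
        )
        inc = coh.endpoints["event"].mean()
        assert abs(inc - 0.063) < 0.012
        share = np.bincount(coh.labels, minlength=2) / len(coh.labels)
        assert abs(share.min() - 0.167) < 0.02
        t_cens = coh.endpoints.query("event == 0")["censor_age"]
        followed_6 = (
            (t_cens >= 6).sum() + (coh.endpoints["event"] == 1).sum()
        ) / len(coh.endpoints)
        assert 0.55 < followed_6 < 0.8  # about 68% followed to 6 years

    def test_seed_determinism_byte_identical(self, tmp_path):
        a = simulate_cohort(CohortConfig(n_subjects=120, seed=77,
                                         followup_max=6.0))
        b = simulate_cohort(CohortConfig(n_subjects=120, seed=77,
                                         followup_max=6.0))
        write_cohort(a, tmp_path / "a")
        write_cohort(b, tmp_path / "b")
        for name in ("baseline.csv", "long.csv", "endpoints.csv",
                     "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_visit_schedule_covers_protocol_gaps(self):
        v = default_antibody_visits(15.0)
        gaps = np.diff(np.concatenate([[0.0], v]))
        assert gaps.min() >= 0.25 - 1e-12
        assert gaps.max() <= 1.0 + 1e-12
        assert v[-1] == 15.0

    def test_single_class_latent_cohort_matches_jm_generator(self):
        truth = default_jlcmm_truth()
        import dataclasses

        truth1 = dataclasses.replace(
            truth,
            params=dataclasses.replace(
                truth.params, lam=np.zeros(1), beta=truth.params.beta[:1],
                log_heights=truth.params.log_heights[:1],
            ),
        )
        coh = simulate_latent_class_cohort(
            CohortConfig(n_subjects=800, seed=6), truth1
        )
        assert (coh.labels == 0).all()
        # trajectory population mean follows the single class curve
        for age, g in coh.long.groupby("age_years"):
            B = bspline_basis(np.array([age]), truth.spec)[0]
            mean = B @ truth1.params.beta[0]
            sd = np.sqrt(B @ np.diag(truth1.params.d) @ B
                         + truth1.params.sigma2)
            assert abs(g["food_g_day"].mean() - mean) < 4 * sd / np.sqrt(
                max(len(g), 1)
            )
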