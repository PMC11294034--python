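import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from goshawkipm.likelihoods import (
    CJSData,
    LikelihoodContext,
    RecoveryData,
    joint_loglik,
    log_ztpoisson_pmf,
    loglik_adult_cr,
    loglik_breeder_counts,
    loglik_counts,
    loglik_productivity,
    loglik_recovery,
    loglik_sexratio,
    loglik_success,
    transition_loglik,
)
from goshawkipm.population_model import ValidationError
from goshawkipm.synthetic_data import MonitoringData, simulate_dataset

from conftest import random_rates


def _cr_frame(rows, T):
    return pd.DataFrame(rows, columns=["id", "sex", "first_age_class",
                                       "history"])[
        ["id", "sex", "first_age_class", "history"]]


class TestCounts:
    def test_single_year_closed_form(self):
        # Poisson(3; mean 2): 3 log2 - 2 - log 6
        got = loglik_counts([3], [2.0])
        assert got == pytest.approx(3 * math.log(2) - 2 - math.log(6))

    def test_observed_equals_truth(self):
        got = loglik_counts([50] * 4, [50.0] * 4)
        assert got == pytest.approx(4 * stats.poisson.logpmf(50, 50))

    def test_three_year_hand_total(self):
        obs, mean = [4, 7, 2], [5.0, 6.5, 3.0]
        by_hand = sum(k * math.log(m) - m - math.log(math.factorial(k))
                      for k, m in zip(obs, mean))
        assert loglik_counts(obs, mean) == pytest.approx(by_hand)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            loglik_counts([-1], [2.0])


class TestBreederCounts:
    def test_perfect_detection_pins_truth(self):
        obs = np.zeros((2, 2, 3))
        obs[:, :, :] = [[3, 4, 10], [2, 3, 9]]
        p = np.ones((2, 2))
        assert loglik_breeder_counts(obs, obs, p) == pytest.approx(0.0)
        wrong = obs.copy()
        wrong[0, 0, 0] += 1
        assert loglik_breeder_counts(wrong, obs, p) == -np.inf

    def test_none_seen_of_ten(self):
        obs = np.zeros((1, 2, 3))
        true = np.zeros((1, 2, 3))
        true[0, 0, 0] = 10
        p = np.full((1, 2), 0.3)
        assert loglik_breeder_counts(obs, true, p) == pytest.approx(
            10 * math.log(0.7))

    def test_matches_enumeration_on_two_classes(self):
        # total probability over all observable outcomes equals 1
        true = np.zeros((1, 2, 3))
        true[0, 0, 0], true[0, 0, 1] = 3, 2
        p = np.full((1, 2), 0.4)
        tot = 0.0
        for k1 in range(4):
            for k2 in range(3):
                obs = np.zeros((1, 2, 3))
                obs[0, 0, 0], obs[0, 0, 1] = k1, k2
                tot += math.exp(loglik_breeder_counts(obs, true, p))
        assert tot == pytest.approx(1.0)


class TestBroodComponents:
    def test_single_success(self):
        df = pd.DataFrame([{"year": 0, "age_class": 2, "success": 1}])
        eta = np.full((1, 3), 0.8)
        assert loglik_success(df, eta) == pytest.approx(math.log(0.8))

    def test_bernoulli_sum_is_binomial_kernel(self):
        rows = [{"year": 0, "age_class": 1, "success": int(i < 7)}
                for i in range(10)]
        eta = np.full((1, 3), 0.6)
        got = loglik_success(pd.DataFrame(rows), eta)
        assert got == pytest.approx(7 * math.log(0.6) + 3 * math.log(0.4))

    def test_mixed_age_hand_total(self):
        rows = [{"year": 0, "age_class": 1, "success": 1},
                {"year": 0, "age_class": 3, "success": 0},
                {"year": 1, "age_class": 3, "success": 1}]
        eta = np.array([[0.4, 0.5, 0.9], [0.4, 0.5, 0.7]])
        want = math.log(0.4) + math.log(0.1) + math.log(0.7)
        assert loglik_success(pd.DataFrame(rows), eta) == pytest.approx(want)

    def test_ztpoisson_single_count(self):
        df = pd.DataFrame([{"year": 0, "age_class": 1, "count": 1}])
        rho = np.ones((1, 3))
        want = math.log(math.exp(-1) / (1 - math.exp(-1)))
        assert loglik_productivity(df, rho) == pytest.approx(want)

    def test_ztpoisson_normalizes(self):
        for lam in (0.3, 1.0, 2.5, 6.0):
            ks = np.arange(1, 200)
            total = np.exp(log_ztpoisson_pmf(ks, lam)).sum()
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_truncated_mean_exceeds_rate(self):
        ks = np.arange(1, 400)
        for lam in (0.2, 0.9, 2.2, 4.0):
            pmf = np.exp(log_ztpoisson_pmf(ks, lam))
            assert (ks * pmf).sum() > lam

    def test_zero_count_rejected(self):
        df = pd.DataFrame([{"year": 0, "age_class": 1, "count": 0}])
        with pytest.raises(ValidationError):
            loglik_productivity(df, np.ones((1, 3)))

    def test_sexratio_closed_form(self):
        df = pd.DataFrame([{"year": 0, "age_class": 2,
                            "n_female": 2, "n_male": 2}])
        xi = np.full((1, 3), 0.5)
        assert loglik_sexratio(df, xi) == pytest.approx(math.log(6 / 16))

    def test_sexratio_impossible_female(self):
        df = pd.DataFrame([{"year": 0, "age_class": 1,
                            "n_female": 1, "n_male": 3}])
        assert loglik_sexratio(df, np.zeros((1, 3))) == -np.inf


class TestCJS:
    def test_two_occasion_death(self):
        T = 2
        s = np.full((T, 3, 2), 0.5)
        p = np.ones((T, 2))
        df = _cr_frame([{"id": 0, "sex": "f", "first_age_class": 3,
                         "history": "10"}], T)
        assert loglik_adult_cr(df, s, p) == pytest.approx(math.log(0.5))
        df2 = _cr_frame([{"id": 0, "sex": "f", "first_age_class": 3,
                          "history": "11"}], T)
        assert loglik_adult_cr(df2, s, p) == pytest.approx(math.log(0.5))

    def test_continuations_sum_to_one(self):
        rng = np.random.default_rng(4)
        T = 5
        s = rng.uniform(0.2, 0.95, (T, 3, 2))
        p = rng.uniform(0.1, 0.95, (T, 2))
        for age0 in (1, 2, 3):
            total = 0.0
            for cont in itertools.product([0, 1], repeat=T - 1):
                h = "1" + "".join(map(str, cont))
                df = _cr_frame([{"id": 0, "sex": "m",
                                 "first_age_class": age0, "history": h}], T)
                total += math.exp(loglik_adult_cr(df, s, p))
            assert total == pytest.approx(1.0)

    def test_m_array_equals_individual_histories(self):
        rng = np.random.default_rng(8)
        T = 9
        rows = []
        for i in range(60):
            first = rng.integers(0, T - 1)
            h = np.zeros(T, dtype=int)
            h[first] = 1
            h[first + 1:] = rng.random(T - first - 1) < 0.35
            rows.append({"id": i, "sex": "fm"[rng.integers(2)],
                         "first_age_class": int(rng.integers(1, 4)),
                         "history": "".join(map(str, h))})
        cjs = CJSData.from_frame(_cr_frame(rows, T), T)
        for _ in range(5):
            s = rng.uniform(0.2, 0.95, (T, 3, 2))
            p = rng.uniform(0.1, 0.95, (T, 2))
            assert cjs.loglik(s, p) == pytest.approx(
                cjs.loglik_individual(s, p), rel=1e-10)

    def test_malformed_history_rejected(self):
        df = _cr_frame([{"id": 0, "sex": "f", "first_age_class": 1,
                         "history": "0000"}], 4)
        with pytest.raises(ValidationError):
            CJSData.from_frame(df, 4)


class TestRecovery:
    def test_first_interval_closed_form(self):
        T = 4
        s = np.full((T, 3, 2), 0.9)
        s[:, 0, :] = 0.6
        r = np.full((T, 2), 0.5)
        df = pd.DataFrame([{"id": 0, "sex": "f", "ring_year": 0,
                            "recovery_year": 1}])
        assert loglik_recovery(df, s, r) == pytest.approx(math.log(0.2))

    def test_certain_recovery_censored_is_survival(self):
        T = 4
        rng = np.random.default_rng(1)
        s = rng.uniform(0.3, 0.9, (T, 3, 2))
        r = np.ones((T, 2))
        df = pd.DataFrame([{"id": 0, "sex": "m", "ring_year": 0,
                            "recovery_year": -1}])
        # survival through intervals 0,1,2 with ages s1, s2, s3
        want = math.log(s[0, 0, 1] * s[1, 1, 1] * s[2, 2, 1])
        assert loglik_recovery(df, s, r) == pytest.approx(want)

    def test_event_probabilities_sum_to_one(self):
        T = 6
        rng = np.random.default_rng(2)
        s = rng.uniform(0.2, 0.9, (T, 3, 2))
        r = rng.uniform(0.05, 0.9, (T, 2))
        rd = RecoveryData(D=np.zeros((2, T, T - 1)), C=np.zeros((2, T)), T=T)
        P, Pc = rd.interval_logprobs(s, r)
        assert np.allclose(P.sum(axis=2) + Pc, 1.0)


class TestJointLikelihood:
    @staticmethod
    def _empty_data(T, counts=None):
        cols = {
            "territory_counts": ["year", "count"],
            "breeder_counts": ["year", "sex", "age_class", "count"],
            "brood_success": ["year", "age_class", "success"],
            "brood_fledglings": ["year", "age_class", "count"],
            "brood_sex": ["year", "age_class", "n_female", "n_male"],
            "adult_cr": ["id", "sex", "first_age_class", "history"],
            "recoveries": ["id", "sex", "ring_year", "recovery_year"],
        }
        frames = {k: pd.DataFrame(columns=v) for k, v in cols.items()}
        if counts is not None:
            frames["territory_counts"] = pd.DataFrame(
                {"year": range(T), "count": counts})
        return MonitoringData(T, **frames)

    @staticmethod
    def _context(seed=0, T=4):
        rng = np.random.default_rng(seed)
        rates = [random_rates(rng) for _ in range(T)]
        F = rng.integers(1, 12, (T, 5))
        M = rng.integers(1, 12, (T, 6))
        p = rng.uniform(0.3, 0.9, (T, 2))
        r = rng.uniform(0.05, 0.5, (T, 2))
        return LikelihoodContext.from_rates(F, M, rates, p, r)

    def test_empty_data_leaves_transition_density(self):
        ctx = self._context()
        data = self._empty_data(ctx.n_years)
        assert joint_loglik(data, ctx) == pytest.approx(transition_loglik(ctx))

    def test_additivity_of_components(self):
        data, hist = simulate_dataset(seed=31, years=6)
        tr = hist.trajectory
        rng = np.random.default_rng(3)
        p = rng.uniform(0.3, 0.9, (6, 2))
        r = rng.uniform(0.05, 0.5, (6, 2))
        ctx = LikelihoodContext.from_rates(tr.females, tr.males, tr.rates,
                                           p, r)
        total = joint_loglik(data, ctx)
        parts = (
            transition_loglik(ctx)
            + loglik_counts(data.territory_counts["count"].to_numpy(),
                            ctx.pairs())
            + loglik_breeder_counts(data.breeder_counts_array(),
                                    ctx.breeder_class_counts(), ctx.p)
            + loglik_success(data.brood_success, ctx.eta)
            + loglik_productivity(data.brood_fledglings, ctx.rho)
            + loglik_sexratio(data.brood_sex, ctx.xi)
            + loglik_adult_cr(data.adult_cr, ctx.s, ctx.p)
            + loglik_recovery(data.recoveries, ctx.s, ctx.r))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_record_order_invariance(self):
        data, hist = simulate_dataset(seed=32, years=6)
        tr = hist.trajectory
        p = np.full((6, 2), 0.6)
        r = np.full((6, 2), 0.2)
        ctx = LikelihoodContext.from_rates(tr.females, tr.males, tr.rates,
                                           p, r)
        a = joint_loglik(data, ctx)
        rng = np.random.default_rng(0)
        shuffled = MonitoringData(
            data.n_years, data.territory_counts,
            data.breeder_counts.sample(frac=1, random_state=1),
            data.brood_success.sample(frac=1, random_state=2),
            data.brood_fledglings.sample(frac=1, random_state=3),
            data.brood_sex.sample(frac=1, random_state=4),
            data.adult_cr.sample(frac=1, random_state=5),
            data.recoveries.sample(frac=1, random_state=6))
        assert joint_loglik(shuffled, ctx) == pytest.approx(a, rel=1e-12)

    def test_impossible_latent_state_is_minus_inf_not_raise(self):
        ctx = self._context(seed=5)
        data = self._empty_data(ctx.n_years)
        obs = np.zeros((ctx.n_years, 2, 3))
        obs[0, 0, 0] = 10_000
        assert loglik_breeder_counts(obs, ctx.breeder_class_counts(),
                                     ctx.p) == -np.inf

    def test_three_year_hand_computed_toy(self):
        """Fully hand-checkable instance: one brood, one count, one history."""
        T = 3
        rates = []
        rng = np.random.default_rng(9)
        for _ in range(T):
            rates.append(random_rates(rng))
        F = np.array([[0, 2, 0, 0, 0]] * T)
        M = np.array([[0, 0, 0, 0, 2, 0]] * T)
        p = np.full((T, 2), 0.5)
        r = np.full((T, 2), 0.5)
        ctx = LikelihoodContext.from_rates(F, M, rates, p, r)
        data = self._empty_data(T, counts=[2, 2, 2])
        data.brood_success = pd.DataFrame(
            [{"year": 1, "age_class": 1, "success": 1}])
        got = joint_loglik(data, ctx)
        want = transition_loglik(ctx)
        for t in range(T):
            want += 2 * math.log(2.0) - 2.0 - math.log(2.0)   # Poisson(2;2)
        want += math.log(rates[1].eta[0])
        assert got == pytest.approx(want, rel=1e-12)


def test_transition_marginal_equals_split_enumeration():
    """The stage-4 recruit/survivor split summed out matches the joint
    trinomial-times-binomial enumeration."""
    from goshawkipm.likelihoods import _stage34_marginal_loglik
    rng = np.random.default_rng(12)
    for _ in range(30):
        n1, n2 = rng.integers(0, 12, 2)
        s2, a2 = rng.uniform(0.2, 0.9), rng.uniform(0.1, 0.9)
        total = 0.0
        for n3 in range(n1 + 1):
            for n4 in range(n1 + n2 + 1):
                lp = _stage34_marginal_loglik(n1, n2, n3, n4, s2, a2)
                total += math.exp(lp)
        assert total == pytest.approx(1.0, abs=1e-9)
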