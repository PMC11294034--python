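import numpy as np
import pytest
from scipy import stats

from goshawkipm.population_model import (
    DemographicHyperParams,
    DemographicRatesYear,
    PopulationState,
    ValidationError,
    annual_growth_rates,
    expected_next_state,
    expected_projection_matrix,
    geometric_mean_growth,
    project_trajectory,
    stochastic_next_state,
)

from conftest import random_rates


def _state(f, m):
    return PopulationState(f=np.asarray(f, dtype=np.int64),
                           m=np.asarray(m, dtype=np.int64))


def _zero_rates(**kw):
    base = dict(s=np.zeros((3, 2)), eta=np.zeros(3), rho=np.zeros(3),
                xi=np.full(3, 0.5), alpha=np.zeros((2, 2)), omega=0.0)
    base.update(kw)
    return DemographicRatesYear(**base)


class TestExpectedNextState:
    def test_all_rates_zero_annihilates(self):
        st = _state([3, 4, 5, 6, 7], [1, 2, 3, 4, 5, 6])
        out = expected_next_state(st, _zero_rates(), _zero_rates())
        assert np.allclose(out, 0.0)

    def test_matriarch_production_closed_form(self):
        # ten 3y+ breeding females, eta3=.8, rho3=2.5, xi3=.5, s1f=.4,
        # next year's alpha1f=.2: E[N1f] = 10*.8*2.5*.5*.4*.8 = 3.2
        st = _state([0, 0, 0, 0, 10], [0] * 6)
        r = _zero_rates(s=np.array([[0.4, 0.4], [0, 0], [0, 0]]),
                        eta=np.array([0, 0, 0.8]), rho=np.array([0, 0, 2.5]))
        rn = _zero_rates(alpha=np.array([[0.2, 0.0], [0.0, 0.0]]))
        out = expected_next_state(st, r, rn)
        assert out[0] == pytest.approx(3.2)
        assert out[1] == pytest.approx(0.8)

    def test_immigrant_expectation_is_next_years_omega(self):
        st = _state([0, 0, 0, 0, 1], [0] * 6)
        out = expected_next_state(st, _zero_rates(),
                                  _zero_rates(omega=3.7))
        assert out[10] == pytest.approx(3.7)

    def test_matches_monte_carlo_mean(self):
        rng = np.random.default_rng(42)
        st = _state([12, 5, 7, 9, 30], [10, 3, 6, 8, 25, 2])
        r, rn = random_rates(rng), random_rates(rng)
        exp = expected_next_state(st, r, rn)
        F, M = stochastic_next_state(st, r, rn, rng, size=100_000)
        emp = np.concatenate([F.mean(0), M.mean(0)])
        se = np.concatenate([F.std(0), M.std(0)]) / np.sqrt(100_000)
        assert np.all(np.abs(emp - exp) <= 3 * np.maximum(se, 1e-12))

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValidationError):
            _zero_rates(eta=np.array([0.5, 1.2, 0.5]))
        with pytest.raises(ValidationError):
            _zero_rates(rho=np.array([1.0, -0.1, 1.0]))
        with pytest.raises(ValidationError):
            _state([1, -1, 0, 0, 0], [0] * 6)


class TestStochasticNextState:
    def test_certain_survival_is_deterministic(self):
        r = _zero_rates(s=np.ones((3, 2)), alpha=np.ones((2, 2)))
        st = _state([0, 0, 0, 0, 5], [0, 0, 0, 0, 5, 0])
        rng = np.random.default_rng(0)
        for _ in range(10):
            st = stochastic_next_state(st, r, r, rng)
            assert st.f[4] == 5 and st.m[4] == 5
            assert st.f[:4].sum() == 0 and st.m[[0, 1, 2, 3, 5]].sum() == 0

    def test_zero_first_year_survival_blocks_recruits(self):
        rng = np.random.default_rng(1)
        r = random_rates(rng)
        r.s[0] = 0.0
        st = _state([5, 10, 5, 10, 30], [5, 10, 5, 10, 30, 2])
        nxt = stochastic_next_state(st, r, random_rates(rng), rng)
        assert nxt.f[0] == 0 and nxt.f[1] == 0
        assert nxt.m[0] == 0 and nxt.m[1] == 0

    def test_stage4_recruitment_distribution(self):
        # 20 female floaters, s2f=.5, alpha2f(t+1)=.6, no stage-2 females:
        # N4f' ~ Binomial(20, .3)
        r = _zero_rates(s=np.array([[0, 0], [0.5, 0], [0, 0]]))
        rn = _zero_rates(alpha=np.array([[0, 0], [0.6, 0]]))
        st = _state([20, 0, 0, 0, 0], [0] * 6)
        rng = np.random.default_rng(5)
        F, _ = stochastic_next_state(st, r, rn, rng, size=100_000)
        obs = np.bincount(F[:, 3], minlength=21)
        exp = stats.binom.pmf(np.arange(21), 20, 0.3) * 100_000
        keep = exp > 5
        chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        crit = stats.chi2.ppf(0.99, keep.sum() - 1)
        assert chi2 < crit

    def test_survivors_never_exceed_pool(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            st = _state(rng.integers(0, 30, 5), rng.integers(0, 30, 6))
            r, rn = random_rates(rng), random_rates(rng)
            nxt = stochastic_next_state(st, r, rn, rng)
            assert nxt.f[2] + nxt.f[3] <= st.f[0] + st.f[1]
            assert nxt.f[4] <= st.f[2] + st.f[3] + st.f[4]
            assert nxt.m[4] <= st.m[2] + st.m[3] + st.m[4] + st.m[5]

    def test_sex_symmetry_of_expectations(self):
        rng = np.random.default_rng(11)
        r = random_rates(rng, omega=0.0)
        r.s[:, 1] = r.s[:, 0]
        r.alpha[:, 1] = r.alpha[:, 0]
        r.xi[:] = 0.5
        st = _state([8, 6, 4, 7, 20], [8, 6, 4, 7, 20, 0])
        out = expected_next_state(st, r, r)
        assert np.allclose(out[:5], out[5:10])

    def test_monotone_in_survival(self):
        rng = np.random.default_rng(13)
        st = _state([8, 6, 4, 7, 20], [8, 6, 4, 7, 20, 1])
        r, rn = random_rates(rng), random_rates(rng)
        lo = expected_next_state(st, r, rn)
        r2 = DemographicRatesYear(s=np.minimum(r.s * 1.1, 1.0), eta=r.eta,
                                  rho=r.rho, xi=r.xi, alpha=r.alpha,
                                  omega=r.omega)
        hi = expected_next_state(st, r2, rn)
        assert np.all(hi >= lo - 1e-12)


class TestProjection:
    def test_expected_mode_equals_repeated_expectation(self):
        rng = np.random.default_rng(2)
        means = random_rates(rng).to_dict()
        hyper = DemographicHyperParams.from_natural_means(means)
        st = _state([10, 5, 5, 5, 20], [10, 5, 5, 5, 20, 2])
        traj = project_trajectory(st, hyper, 6, mode="expected")
        vec = st.as_vector()
        r = hyper.mean_rates()
        for t in range(5):
            M = expected_projection_matrix(r, r)
            vec = M @ vec
            vec[10] += r.omega
            assert np.allclose(traj.females[t + 1], vec[:5])
            assert np.allclose(traj.males[t + 1], vec[5:])

    def test_fixed_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        means = random_rates(rng).to_dict()
        hyper = DemographicHyperParams.from_natural_means(
            means, {k: 0.2 for k in means})
        st = _state([10, 5, 5, 5, 20], [10, 5, 5, 5, 20, 2])
        a = project_trajectory(st, hyper, 10, seed=99)
        b = project_trajectory(st, hyper, 10, seed=99)
        assert np.array_equal(a.females, b.females)
        assert np.array_equal(a.males, b.males)

    def test_too_few_years_rejected(self):
        hyper = DemographicHyperParams.from_natural_means(
            random_rates(np.random.default_rng(0)).to_dict())
        st = _state([1, 1, 1, 1, 10], [1, 1, 1, 1, 10, 0])
        with pytest.raises(ValidationError):
            project_trajectory(st, hyper, 1)


class TestGrowthRates:
    def test_constant_trajectory_gives_unit_growth(self):
        lam = annual_growth_rates(np.full(10, 42.0))
        assert np.allclose(lam, 1.0)
        assert geometric_mean_growth(np.full(10, 42.0)) == pytest.approx(1.0)

    def test_doubling_gives_two(self):
        n = 5.0 * 2 ** np.arange(8)
        assert geometric_mean_growth(n) == pytest.approx(2.0)

    def test_geometric_mean_telescopes(self):
        rng = np.random.default_rng(7)
        n = rng.uniform(5, 200, size=25)
        g = geometric_mean_growth(n)
        assert g == pytest.approx((n[-1] / n[0]) ** (1 / (len(n) - 1)),
                                  rel=1e-12)

    def test_extinct_population_rejected(self):
        with pytest.raises(ValidationError):
            annual_growth_rates(np.array([5.0, 0.0, 3.0]))

    def test_trajectory_population_definitions(self):
        F = np.array([[1, 2, 3, 4, 5], [2, 3, 4, 5, 6]], dtype=float)
        M = np.array([[1, 1, 1, 1, 1, 1], [2, 2, 2, 2, 2, 2]], dtype=float)
        traj_rates = []
        from goshawkipm.population_model import Trajectory
        traj = Trajectory(females=F, males=M, rates=traj_rates)
        assert np.allclose(traj.totals("pairs"), [2 + 4 + 5, 3 + 5 + 6])
        assert np.allclose(traj.totals("females"), [15, 20])
        assert np.allclose(traj.totals("all"), [21, 32])
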