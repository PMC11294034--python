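import numpy as np
import pytest

import goshawkipm.perturbation as pt
from goshawkipm.inference import PosteriorDraws
from goshawkipm.population_model import (
    DemographicHyperParams,
    DemographicRatesYear,
    PopulationState,
    Trajectory,
    ValidationError,
    expected_projection_matrix,
    expected_trajectory,
    project_trajectory,
)

from conftest import random_rates


def _constant_trajectory(rates_dict, females, males, T=4):
    r = DemographicRatesYear.from_dict(rates_dict)
    F = np.tile(np.asarray(females, dtype=float), (T, 1))
    M = np.tile(np.asarray(males, dtype=float), (T, 1))
    return Trajectory(females=F, males=M, rates=[r] * T)


def _base_rates(**kw):
    d = {n: 0.0 for n in
         ("s1f", "s1m", "s2f", "s2m", "s3f", "s3m", "alpha1f", "alpha1m",
          "alpha2f", "alpha2m", "omega")}
    d.update({f"eta{a}": 0.0 for a in (1, 2, 3)})
    d.update({f"rho{a}": 0.0 for a in (1, 2, 3)})
    d.update({f"xi{a}": 0.5 for a in (1, 2, 3)})
    d.update(kw)
    return d


def test_matrix_builder_matches_projection_core():
    rng = np.random.default_rng(6)
    r = random_rates(rng)
    vals = r.to_dict()
    assert np.allclose(np.real(pt._build_matrix(vals)),
                       expected_projection_matrix(r, r))


def test_closed_form_elasticity_in_survival_fecundity_reduction():
    """With everybody in the 3y+ female stage, xi = 1 and no first-year
    recruitment, lambda = s3f + eta3*rho3*s1f; the elasticities are the
    relative shares of the two pathways."""
    s3f, eta3, rho3, s1f = 0.8, 0.75, 2.0, 0.3
    vals = _base_rates(s3f=s3f, eta3=eta3, rho3=rho3, s1f=s1f, xi3=1.0)
    traj = _constant_trajectory(vals, [0, 0, 0, 0, 50], [0] * 6)
    post = PosteriorDraws.from_trajectories([traj])
    el = pt.transient_elasticities(post)
    lam = s3f + eta3 * rho3 * s1f
    assert el.values["s3f"][0] == pytest.approx(s3f / lam, rel=1e-8)
    assert el.values["s1f"][0] == pytest.approx(eta3 * rho3 * s1f / lam,
                                                rel=1e-8)
    assert el.values["eta3"][0] == pytest.approx(eta3 * rho3 * s1f / lam,
                                                 rel=1e-8)
    # immigration does not operate in this all-female reduction
    assert el.values["omega"][0] == 0.0
    assert el.values["s2m"][0] == 0.0


def test_elasticities_match_finite_difference_quickly(desk_posterior):
    """Spot check on a handful of draws (the full sweep runs in the
    acceptance suite)."""
    post = desk_posterior
    el = pt.transient_elasticities(post, max_draws=3, seed=5)
    Nf, Nm = post.stacked("Nf"), post.stacked("Nm")
    idx = pt._draw_indices(post, 3, 5)
    for j, i in enumerate(idx):
        series = pt.rate_series_from_draw(post, i)
        vals = {n: float(np.mean(v)) for n, v in series.items()}
        U = np.concatenate([Nf[i], Nm[i]], axis=1)
        tot = U.sum(axis=1)
        u = (U / tot[:, None]).mean(axis=0)
        ntot = float(tot.mean())
        lam = pt.lambda_fn(vals, u, ntot)
        for name in ("s1f", "s3m", "eta3", "omega"):
            h = 1e-4 * vals[name]
            hi, lo = dict(vals), dict(vals)
            hi[name] += h
            lo[name] -= h
            fd = (pt.lambda_fn(hi, u, ntot) - pt.lambda_fn(lo, u, ntot)) / (2 * h)
            want = vals[name] * fd / lam
            assert el.values[name][j] == pytest.approx(want, rel=1e-3)


def test_constant_rate_contributes_nothing():
    rng = np.random.default_rng(3)
    means = random_rates(rng).to_dict()
    means.update(omega=1.5, s3f=0.8, s3m=0.8)
    hyper = DemographicHyperParams.from_natural_means(
        means, {k: (0.0 if k == "omega" else 0.15) for k in means})
    init = PopulationState(f=np.array([20, 10, 10, 10, 60], dtype=np.int64),
                           m=np.array([20, 10, 10, 10, 60, 2], dtype=np.int64))
    trajs = [project_trajectory(init, hyper, 25, seed=s) for s in range(3)]
    post = PosteriorDraws.from_trajectories(trajs)
    res = pt.ltre_contributions(post)
    assert np.allclose(res.values["omega"], 0.0, atol=1e-12)
    total = sum(res.values[k] for k in res.values)
    assert np.allclose(total, 1.0)
    assert np.allclose(res.extras["direct"] + res.extras["structure"], 1.0)


def test_first_order_variance_matches_realized_on_small_noise():
    """Without demographic noise and with small rate variation, the LTRE
    first-order variance reproduces the realized var(lambda_t)."""
    rng = np.random.default_rng(4)
    means = {"s1f": 0.32, "s1m": 0.28, "s2f": 0.65, "s2m": 0.63,
             "s3f": 0.80, "s3m": 0.79, "eta1": 0.55, "eta2": 0.72,
             "eta3": 0.82, "rho1": 2.1, "rho2": 2.5, "rho3": 2.6,
             "xi1": 0.45, "xi2": 0.46, "xi3": 0.47, "alpha1f": 0.45,
             "alpha1m": 0.12, "alpha2f": 0.55, "alpha2m": 0.55,
             "omega": 2.0}
    hyper = DemographicHyperParams.from_natural_means(
        means, {k: 0.05 for k in means})
    init = PopulationState(f=np.array([30, 12, 12, 18, 90], dtype=np.int64),
                           m=np.array([25, 6, 10, 15, 85, 2], dtype=np.int64))
    ratios = []
    for s in range(6):
        rates = hyper.draw_rates(60, np.random.default_rng(100 + s))
        traj = expected_trajectory(init, rates)
        post = PosteriorDraws.from_trajectories([traj])
        res = pt.ltre_contributions(post)
        ratios.append(res.extras["var_first_order"][0]
                      / res.extras["var_realized"][0])
    assert abs(np.median(ratios) - 1.0) < 0.10


def test_stochasticity_shares_partition():
    rng = np.random.default_rng(8)
    means = random_rates(rng).to_dict()
    means.update(s3f=0.85, s3m=0.85)
    # deterministic "actual" trajectory: demographic share is exactly zero
    hyper = DemographicHyperParams.from_natural_means(
        means, {k: 0.2 for k in means})
    rates = hyper.draw_rates(20, rng)
    init = PopulationState(f=np.array([20, 10, 10, 10, 50], dtype=np.int64),
                           m=np.array([20, 10, 10, 10, 50, 2], dtype=np.int64))
    det = expected_trajectory(init, rates)
    post = PosteriorDraws.from_trajectories([det])
    res = pt.stochasticity_decomposition(post)
    assert res.values["env_share"][0] == pytest.approx(1.0)
    assert np.allclose(res.values["env_share"] + res.values["dem_share"], 1.0)
    # no environmental variation: only a small transient-structure residue
    # remains in the environmental-only growth rates
    hyper0 = DemographicHyperParams.from_natural_means(means)
    trajs = [project_trajectory(init, hyper0, 20, seed=s) for s in range(5)]
    post0 = PosteriorDraws.from_trajectories(trajs)
    res0 = pt.stochasticity_decomposition(post0)
    assert res0.values["env_share"].mean() < 0.05


def test_derived_summaries_hand_checked():
    vals = _base_rates(eta3=1.0, rho3=2.0, s3f=0.9, s3m=0.9, xi3=0.5)
    r = DemographicRatesYear.from_dict(vals)
    F = np.array([[2, 2, 2, 2, 4], [2, 2, 2, 2, 14], [2, 2, 2, 2, 44]],
                 dtype=float)
    M = np.array([[1, 1, 1, 1, 4, 0]] * 3, dtype=float)
    traj = Trajectory(females=F, males=M, rates=[r] * 3)
    post = PosteriorDraws.from_trajectories([traj])
    sm = pt.derived_summaries(post)
    # pairs: 8, 18, 48 -> geometric mean sqrt(6), CV from the raw series
    pairs = np.array([8.0, 18.0, 48.0])
    assert sm.values["geo_mean_lambda"][0] == pytest.approx(np.sqrt(6.0))
    assert sm.values["total_change"][0] == pytest.approx(5.0)
    assert sm.values["cv_pairs"][0] == pytest.approx(
        pairs.std(ddof=1) / pairs.mean())
    assert sm.values["fledged_per_brood_3"][0] == pytest.approx(2.0)
    comp = (sm.values["prop_fledglings"][0] + sm.values["prop_floaters"][0]
            + sm.values["prop_breeders"][0])
    assert comp == pytest.approx(1.0)


def test_degenerate_structure_rejected():
    vals = _base_rates(s3f=0.5)
    traj = _constant_trajectory(vals, [0, 0, 0, 0, 0], [0] * 6)
    post = PosteriorDraws.from_trajectories([traj])
    with pytest.raises(ValidationError):
        pt.transient_elasticities(post)
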