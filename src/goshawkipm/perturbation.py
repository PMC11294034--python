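"""Prospective and retrospective analyses of the realized growth rate.

All quantities are *transient* (real-time): the growth rate analysed is
``lambda_t = N_{t+1} / N_t`` of the realized population (all individuals
aged one year or more, both sexes), not the asymptotic eigenvalue of a
mean matrix.

- *Elasticities* measure the proportional change of ``lambda`` under a
  proportional change of each demographic rate or of each relative
  stage-abundance component, evaluated at the temporal means of rates and
  structure.  Because the expected one-step map is linear in the stage
  vector, ``lambda(theta, u) = 1' M(theta) u + omega / N`` and exact
  derivatives are available by complex-step differentiation.
- *LTRE contributions* decompose the temporal variance of ``lambda_t`` to
  first order into ``sens_i * sens_j * cov(x_i, x_j)`` terms over the
  demographic rates and the structure components; relative contributions
  attribute each row sum to its component, so rate ("direct") and
  structure ("delayed") aggregates add to one.
- The *stochasticity decomposition* propagates the expected
  (demographic-noise-free) trajectory under each draw's realized annual
  rates and splits the variance of ``lambda_t`` into environmental and
  demographic parts.

Every analysis is computed per posterior draw, never by plugging posterior
means into nonlinear functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population_model import (
    RATE_NAMES,
    DemographicRatesYear,
    ValidationError,
    expected_projection_matrix,
)
from .inference import PosteriorDraws

__all__ = [
    "STRUCTURE_NAMES",
    "DrawWiseResult",
    "transient_elasticities",
    "ltre_contributions",
    "stochasticity_decomposition",
    "derived_summaries",
    "rate_series_from_draw",
    "lambda_fn",
]

#: relative stage-structure components (females first)
STRUCTURE_NAMES = tuple(f"u_f{i}" for i in range(1, 6)) + tuple(
    f"u_m{i}" for i in range(1, 7))

_CSTEP = 1e-20


@dataclass
class DrawWiseResult:
    """Per-component posterior distributions of an analysis.

    ``values`` maps component names to (n_draws,) arrays; :meth:`table`
    gives posterior means with equal-tailed 95% CRIs.
    """

    values: dict
    extras: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for k, v in self.values.items():
            lo, hi = np.percentile(v, [2.5, 97.5])
            rows.append({"component": k, "mean": float(np.mean(v)),
                         "cri_lo": float(lo), "cri_hi": float(hi)})
        return pd.DataFrame(rows)


def _build_matrix(vals: dict) -> np.ndarray:
    """11x11 expected projection matrix from a flat rate mapping.

    Accepts complex entries (for complex-step derivatives); mirrors
    :func:`~goshawkipm.population_model.expected_projection_matrix`.
    """
    dtype = complex if any(isinstance(v, complex) for v in vals.values()) \
        else float
    M = np.zeros((11, 11), dtype=dtype)
    for a, c in enumerate((1, 3, 4)):
        per = vals[f"eta{a + 1}"] * vals[f"rho{a + 1}"]
        fem = per * vals[f"xi{a + 1}"]
        mal = per * (1.0 - vals[f"xi{a + 1}"])
        M[0, c] = fem * vals["s1f"] * (1.0 - vals["alpha1f"])
        M[1, c] = fem * vals["s1f"] * vals["alpha1f"]
        M[5, c] = mal * vals["s1m"] * (1.0 - vals["alpha1m"])
        M[6, c] = mal * vals["s1m"] * vals["alpha1m"]
    M[2, 0] = vals["s2f"] * (1.0 - vals["alpha2f"])
    M[3, 0] = vals["s2f"] * vals["alpha2f"]
    M[3, 1] = vals["s2f"]
    M[4, 2] = M[4, 3] = M[4, 4] = vals["s3f"]
    M[7, 5] = vals["s2m"] * (1.0 - vals["alpha2m"])
    M[8, 5] = vals["s2m"] * vals["alpha2m"]
    M[8, 6] = vals["s2m"]
    M[9, 7] = M[9, 8] = M[9, 9] = M[9, 10] = vals["s3m"]
    return M


def lambda_fn(vals: dict, u: np.ndarray, n_total: float):
    """Realized one-step growth rate at rates ``vals`` and structure ``u``.

    ``u`` is the (11,) relative stage-abundance vector; immigration adds
    ``omega / n_total`` because it is an absolute influx.
    """
    M = _build_matrix(vals)
    return np.sum(M @ u) + vals["omega"] / n_total


def _sensitivities(vals: dict, u: np.ndarray, n_total: float):
    """Exact partial derivatives of lambda at (vals, u) via complex step."""
    s_rate = {}
    for name in RATE_NAMES:
        pert = dict(vals)
        pert[name] = vals[name] + 1j * _CSTEP
        s_rate[name] = float(np.imag(lambda_fn(pert, u, n_total)) / _CSTEP)
    colsum = np.asarray(_build_matrix(vals)).sum(axis=0)
    s_struct = {nm: float(colsum[j]) for j, nm in enumerate(STRUCTURE_NAMES)}
    return s_rate, s_struct


def rate_series_from_draw(post: PosteriorDraws, i: int) -> dict:
    """Natural-scale (T,) series of every demographic rate for draw ``i``."""
    return {n: post.stacked(n)[i] for n in RATE_NAMES}


def _structure_series(Nf: np.ndarray, Nm: np.ndarray):
    tot = Nf.sum(axis=1) + Nm.sum(axis=1)
    if np.any(tot <= 0):
        raise ValidationError("zero total abundance: structure undefined")
    U = np.concatenate([Nf, Nm], axis=1) / tot[:, None]
    return U, tot


def _draw_indices(post: PosteriorDraws, max_draws: int,
                  seed: int) -> np.ndarray:
    n = post.n_draws
    if n <= max_draws:
        return np.arange(n)
    return np.random.default_rng(seed).choice(n, size=max_draws,
                                              replace=False)


def transient_elasticities(post: PosteriorDraws, max_draws: int = 400,
                           seed: int = 0) -> DrawWiseResult:
    """Posterior elasticities of realized growth to rates and structure.

    Per draw, rates and relative structure are averaged over years and the
    proportional sensitivity ``(x / lambda) dlambda/dx`` is evaluated
    there.
    """
    idx = _draw_indices(post, max_draws, seed)
    Nf, Nm = post.stacked("Nf"), post.stacked("Nm")
    out = {k: np.empty(len(idx)) for k in RATE_NAMES + STRUCTURE_NAMES}
    for j, i in enumerate(idx):
        series = rate_series_from_draw(post, i)
        vals = {n: float(np.mean(v)) for n, v in series.items()}
        U, tot = _structure_series(Nf[i], Nm[i])
        u = U.mean(axis=0)
        ntot = float(tot.mean())
        lam = float(np.real(lambda_fn(vals, u, ntot)))
        s_rate, s_struct = _sensitivities(vals, u, ntot)
        for n in RATE_NAMES:
            out[n][j] = vals[n] * s_rate[n] / lam
        for k, nm in enumerate(STRUCTURE_NAMES):
            out[nm][j] = u[k] * s_struct[nm] / lam
    return DrawWiseResult(values=out)


#: rates whose destination-year value drives the transition from t
_LOOKAHEAD = ("alpha1f", "alpha1m", "alpha2f", "alpha2m", "omega")


def ltre_contributions(post: PosteriorDraws, max_draws: int = 400,
                       seed: int = 0) -> DrawWiseResult:
    """Retrospective (transient-LTRE) contributions to var(lambda_t).

    First-order decomposition ``var(lambda) ~ sum_ij s_i s_j cov(x_i,
    x_j)`` over demographic rates and structure components, reported as
    relative row-sum contributions; ``extras`` carries the rate
    ("direct") and structure ("delayed") aggregates, and the first-order
    and realized variances.
    """
    if post.n_years < 3:
        raise ValidationError("need at least 3 years for contributions")
    idx = _draw_indices(post, max_draws, seed)
    Nf, Nm = post.stacked("Nf"), post.stacked("Nm")
    names = RATE_NAMES + STRUCTURE_NAMES
    out = {k: np.empty(len(idx)) for k in names}
    agg_direct = np.empty(len(idx))
    agg_struct = np.empty(len(idx))
    var_fo = np.empty(len(idx))
    var_real = np.empty(len(idx))
    T = post.n_years
    for j, i in enumerate(idx):
        series = rate_series_from_draw(post, i)
        U, tot = _structure_series(Nf[i], Nm[i])
        # align each rate with the transition year t -> t+1 it acts on
        X = np.empty((T - 1, len(names)))
        for k, n in enumerate(RATE_NAMES):
            X[:, k] = series[n][1:] if n in _LOOKAHEAD else series[n][:-1]
        X[:, len(RATE_NAMES):] = U[:-1]
        vals = {n: float(np.mean(series[n])) for n in RATE_NAMES}
        u = U.mean(axis=0)
        ntot = float(tot.mean())
        s_rate, s_struct = _sensitivities(vals, u, ntot)
        s = np.array([s_rate[n] for n in RATE_NAMES]
                     + [s_struct[nm] for nm in STRUCTURE_NAMES])
        C = np.cov(X, rowvar=False)
        contrib = (np.outer(s, s) * C)
        total = contrib.sum()
        rows = contrib.sum(axis=1)
        rel = rows / total if total != 0 else np.zeros_like(rows)
        for k, n in enumerate(names):
            out[n][j] = rel[k]
        agg_direct[j] = rel[:len(RATE_NAMES)].sum()
        agg_struct[j] = rel[len(RATE_NAMES):].sum()
        var_fo[j] = total
        lam = tot[1:] / tot[:-1]
        var_real[j] = lam.var(ddof=1)
    return DrawWiseResult(values=out,
                          extras={"direct": agg_direct,
                                  "structure": agg_struct,
                                  "var_first_order": var_fo,
                                  "var_realized": var_real})


def _rates_list(series: dict, T: int) -> list[DemographicRatesYear]:
    return [DemographicRatesYear.from_dict(
        {n: max(float(series[n][t]), 0.0) if n.startswith("rho")
         else float(series[n][t]) for n in RATE_NAMES}) for t in range(T)]


def stochasticity_decomposition(post: PosteriorDraws, max_draws: int = 400,
                                seed: int = 0) -> DrawWiseResult:
    """Environmental vs demographic share of the variance of lambda_t.

    Per draw, the expected (noise-free) trajectory is propagated from the
    realized starting state under the realized annual rates; its growth
    rates carry the environmental variation alone, the residual
    ``lambda_actual - lambda_env`` the demographic part.
    """
    idx = _draw_indices(post, max_draws, seed)
    Nf, Nm = post.stacked("Nf"), post.stacked("Nm")
    env = np.empty(len(idx))
    T = post.n_years
    for j, i in enumerate(idx):
        series = rate_series_from_draw(post, i)
        rates = _rates_list(series, T)
        vec = np.concatenate([Nf[i, 0], Nm[i, 0]]).astype(float)
        etot = [vec.sum()]
        for t in range(T - 1):
            M = expected_projection_matrix(rates[t], rates[t + 1])
            vec = M @ vec
            vec[10] += rates[t + 1].omega
            etot.append(vec.sum())
        etot = np.asarray(etot)
        atot = Nf[i].sum(axis=1) + Nm[i].sum(axis=1)
        lam_env = etot[1:] / etot[:-1]
        lam_act = atot[1:] / atot[:-1]
        lam_dem = lam_act - lam_env
        ve, vd = lam_env.var(ddof=1), lam_dem.var(ddof=1)
        env[j] = ve / (ve + vd) if (ve + vd) > 0 else 1.0
    return DrawWiseResult(values={"env_share": env,
                                  "dem_share": 1.0 - env})


def derived_summaries(post: PosteriorDraws, max_draws: int = 400,
                      seed: int = 0) -> DrawWiseResult:
    """Draw-wise derived population summaries.

    Geometric mean growth and total change of the breeding-pair series,
    its CV, fledglings per initiated brood by maternal age
    (``eta_a * rho_a``), population composition (fledglings / floaters /
    breeders), the breeder decomposition (first-time, experienced,
    immigrant) and the adult sex ratio.
    """
    idx = _draw_indices(post, max_draws, seed)
    Nf, Nm = post.stacked("Nf"), post.stacked("Nm")
    Nf4a = post.stacked("Nf4a") if "Nf4a" in post.draws else None
    Nm4a = post.stacked("Nm4a") if "Nm4a" in post.draws else None
    keys = ["geo_mean_lambda", "total_change", "cv_pairs",
            "fledged_per_brood_1", "fledged_per_brood_2",
            "fledged_per_brood_3", "prop_female_fledglings",
            "prop_fledglings", "prop_floaters", "prop_breeders",
            "adult_sex_ratio",
            "prop_f_first_time", "prop_f_experienced",
            "prop_m_first_time", "prop_m_experienced", "prop_m_immigrant"]
    out = {k: np.empty(len(idx)) for k in keys}
    for j, i in enumerate(idx):
        series = rate_series_from_draw(post, i)
        pairs = Nf[i][:, [1, 3, 4]].sum(axis=1).astype(float)
        if np.any(pairs <= 0):
            raise ValidationError("breeding pairs hit zero in a draw")
        lam = pairs[1:] / pairs[:-1]
        out["geo_mean_lambda"][j] = np.exp(np.mean(np.log(lam)))
        out["total_change"][j] = pairs[-1] / pairs[0] - 1.0
        out["cv_pairs"][j] = pairs.std(ddof=1) / pairs.mean()
        for a in (1, 2, 3):
            out[f"fledged_per_brood_{a}"][j] = float(
                np.mean(series[f"eta{a}"] * series[f"rho{a}"]))
        # composition at the end of a breeding season
        eta = np.stack([series[f"eta{a}"] for a in (1, 2, 3)], axis=1)
        rho = np.stack([series[f"rho{a}"] for a in (1, 2, 3)], axis=1)
        xi = np.stack([series[f"xi{a}"] for a in (1, 2, 3)], axis=1)
        breeders_f = Nf[i][:, [1, 3, 4]].astype(float)
        fled_by_age = breeders_f * eta * rho
        out["prop_female_fledglings"][j] = np.mean(
            (fled_by_age * xi).sum(axis=1)
            / np.maximum(fled_by_age.sum(axis=1), 1e-12))
        fledglings = fled_by_age.sum(axis=1)
        floaters = (Nf[i][:, [0, 2]].sum(axis=1)
                    + Nm[i][:, [0, 2]].sum(axis=1)).astype(float)
        breeders = (pairs + Nm[i][:, [1, 3, 4, 5]].sum(axis=1)).astype(float)
        tot = fledglings + floaters + breeders
        out["prop_fledglings"][j] = np.mean(fledglings / tot)
        out["prop_floaters"][j] = np.mean(floaters / tot)
        out["prop_breeders"][j] = np.mean(breeders / tot)
        adults_m = Nm[i].sum(axis=1).astype(float)
        adults = adults_m + Nf[i].sum(axis=1)
        out["adult_sex_ratio"][j] = np.mean(adults_m / adults)
        if Nf4a is not None:
            first_f = Nf[i][:, 1] + Nf4a[i]
            out["prop_f_first_time"][j] = np.mean(first_f / pairs)
            out["prop_f_experienced"][j] = 1 - out["prop_f_first_time"][j]
            mb = Nm[i][:, [1, 3, 4, 5]].sum(axis=1).astype(float)
            mb = np.maximum(mb, 1.0)
            first_m = Nm[i][:, 1] + Nm4a[i]
            out["prop_m_first_time"][j] = np.mean(first_m / mb)
            out["prop_m_immigrant"][j] = np.mean(Nm[i][:, 5] / mb)
            out["prop_m_experienced"][j] = (1 - out["prop_m_first_time"][j]
                                            - out["prop_m_immigrant"][j])
        else:
            for k in ("prop_f_first_time", "prop_f_experienced",
                      "prop_m_first_time", "prop_m_experienced",
                      "prop_m_immigrant"):
                out[k][j] = np.nan
    return DrawWiseResult(values=out)
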