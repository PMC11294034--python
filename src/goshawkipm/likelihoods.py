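"""Component log-likelihoods of the integrated population model.

The joint likelihood multiplies seven independent data components, all
conditioned on the latent stage-specific abundances and the annual
demographic / observation rates:

1. territory counts — Poisson observation of the number of breeding pairs;
2. sex- and age-class breeder counts — binomial thinning of the true
   breeder stages with the sex/year resighting probability ``p`` (the same
   ``p`` as the capture–recapture component: both data sets come from the
   same feather collections);
3. brood success — Bernoulli with maternal-age-specific ``eta``;
4. fledglings per successful brood — zero-truncated Poisson with rate
   ``rho``;
5. brood sex composition — binomial with maternal-age-specific ``xi``;
6. adult capture–recapture — Cormack–Jolly–Seber likelihood conditioned on
   first identification, with age advancing along the history;
7. dead recoveries of ringed nestlings — Seber-style recovery likelihood
   with sex-specific recovery probability ``r``.

On top of these the latent trajectory itself contributes the state-space
transition density (exact Poisson / binomial / trinomial pmfs — pair counts
are small, so no normal approximation is used).

Data impossible under the latent state (e.g. more breeders observed than
exist) yields ``-inf``, never an exception, so samplers can reject.

Rate sequences are passed as plain arrays: ``s`` has shape ``(T, 3, 2)``
(year, age class, sex with female = column 0), ``eta``/``rho``/``xi`` are
``(T, 3)``, ``alpha`` is ``(T, 2, 2)``, ``omega`` ``(T,)``, ``p``/``r``
``(T, 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .population_model import DemographicRatesYear, ValidationError

__all__ = [
    "LikelihoodContext",
    "CJSData",
    "RecoveryData",
    "BroodStats",
    "loglik_counts",
    "loglik_breeder_counts",
    "loglik_success",
    "loglik_productivity",
    "loglik_sexratio",
    "loglik_adult_cr",
    "loglik_recovery",
    "transition_loglik",
    "joint_loglik",
    "log_poisson_pmf",
    "log_binom_pmf",
    "log_trinomial_pmf",
    "log_ztpoisson_pmf",
]

_NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# elementary log-pmfs (array-friendly, -inf outside the support)


def log_poisson_pmf(k, lam):
    k = np.asarray(k, dtype=float)
    lam = np.asarray(lam, dtype=float)
    out = np.where(lam > 0,
                   k * np.log(np.where(lam > 0, lam, 1.0)) - lam - gammaln(k + 1),
                   np.where((k == 0) & (lam == 0), 0.0, _NEG_INF))
    return np.where(k >= 0, out, _NEG_INF)


def log_binom_pmf(k, n, p):
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    valid = (k >= 0) & (k <= n)
    kk = np.where(valid, k, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), _NEG_INF)
        lq = np.where(p < 1, np.log1p(-np.where(p < 1, p, 0.0)), _NEG_INF)
        core = (gammaln(n + 1) - gammaln(kk + 1) - gammaln(n - kk + 1)
                + np.where(kk > 0, kk * lp, 0.0)
                + np.where(n - kk > 0, (n - kk) * lq, 0.0))
    return np.where(valid, core, _NEG_INF)


def log_trinomial_pmf(k1, k2, n, p1, p2):
    """log P(K1=k1, K2=k2) for a trinomial split of ``n`` with cell probs
    ``(p1, p2, 1-p1-p2)``."""
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    n = np.asarray(n, dtype=float)
    k3 = n - k1 - k2
    valid = (k1 >= 0) & (k2 >= 0) & (k3 >= 0)
    k1c = np.where(valid, k1, 0.0)
    k2c = np.where(valid, k2, 0.0)
    k3c = np.where(valid, k3, 0.0)
    p3 = 1.0 - p1 - p2

    def _term(k, p):
        with np.errstate(divide="ignore"):
            return np.where(k > 0,
                            k * np.where(p > 0, np.log(np.maximum(p, 1e-300)),
                                         _NEG_INF),
                            0.0)

    core = (gammaln(n + 1) - gammaln(k1c + 1) - gammaln(k2c + 1)
            - gammaln(k3c + 1)
            + _term(k1c, p1) + _term(k2c, p2) + _term(k3c, p3))
    return np.where(valid, core, _NEG_INF)


def log_ztpoisson_pmf(k, lam):
    """Zero-truncated Poisson log-pmf (support k >= 1, rate ``lam`` > 0)."""
    k = np.asarray(k, dtype=float)
    lam = np.asarray(lam, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.log(-np.expm1(-np.maximum(lam, 1e-300)))
        core = (k * np.log(np.maximum(lam, 1e-300)) - lam - gammaln(k + 1)
                - denom)
    return np.where((k >= 1) & (lam > 0), core, _NEG_INF)


# ---------------------------------------------------------------------------
# prepared data containers


@dataclass
class BroodStats:
    """Sufficient statistics of the brood-level data sets.

    Everything is indexed ``(year, maternal age class)`` with shape (T, 3).
    """

    succ_k: np.ndarray          # successful broods
    succ_n: np.ndarray          # monitored broods
    prod_sum: np.ndarray        # summed fledgling counts of successful broods
    prod_n: np.ndarray          # successful broods with fledgling counts
    prod_const: float           # -sum log(c!) over all counted broods
    sex_kf: np.ndarray          # female fledglings among sexed
    sex_n: np.ndarray           # sexed fledglings
    sex_const: float            # sum log C(n, kf) over all sexed broods

    @classmethod
    def from_frames(cls, brood_success: pd.DataFrame,
                    brood_fledglings: pd.DataFrame,
                    brood_sex: pd.DataFrame, n_years: int) -> "BroodStats":
        succ_k = np.zeros((n_years, 3))
        succ_n = np.zeros((n_years, 3))
        for (y, a), grp in brood_success.groupby(["year", "age_class"]):
            succ_k[y, a - 1] = grp["success"].sum()
            succ_n[y, a - 1] = len(grp)
        prod_sum = np.zeros((n_years, 3))
        prod_n = np.zeros((n_years, 3))
        prod_const = 0.0
        if len(brood_fledglings):
            if (brood_fledglings["count"] < 1).any():
                raise ValidationError(
                    "brood_fledglings: successful broods must have count >= 1")
            for (y, a), grp in brood_fledglings.groupby(["year", "age_class"]):
                prod_sum[y, a - 1] = grp["count"].sum()
                prod_n[y, a - 1] = len(grp)
            prod_const = -float(gammaln(brood_fledglings["count"] + 1).sum())
        sex_kf = np.zeros((n_years, 3))
        sex_n = np.zeros((n_years, 3))
        sex_const = 0.0
        if len(brood_sex):
            tot = brood_sex["n_female"] + brood_sex["n_male"]
            for (y, a), grp in brood_sex.groupby(["year", "age_class"]):
                sex_kf[y, a - 1] = grp["n_female"].sum()
                sex_n[y, a - 1] = (grp["n_female"] + grp["n_male"]).sum()
            sex_const = float((gammaln(tot + 1)
                               - gammaln(brood_sex["n_female"] + 1)
                               - gammaln(brood_sex["n_male"] + 1)).sum())
        return cls(succ_k, succ_n, prod_sum, prod_n, prod_const,
                   sex_kf, sex_n, sex_const)


@dataclass
class CJSData:
    """Capture histories prepared for vectorized CJS evaluation.

    ``h`` is the (n, T) 0/1 matrix; age class advances deterministically
    from the class at first identification.
    """

    h: np.ndarray
    first: np.ndarray
    last: np.ndarray
    sex_idx: np.ndarray          # 0 female, 1 male
    age0: np.ndarray             # age class (1..3) at first identification
    sidx: np.ndarray = field(default=None)   # (n, T-1) survival age index
    T: int = 0

    @classmethod
    def from_frame(cls, adult_cr: pd.DataFrame, n_years: int) -> "CJSData":
        n = len(adult_cr)
        h = np.zeros((n, n_years), dtype=np.int8)
        for i, hist in enumerate(adult_cr["history"]):
            hist = str(hist)
            if len(hist) != n_years:
                raise ValidationError(
                    f"adult_cr row {i}: history length {len(hist)} != {n_years}")
            h[i] = np.frombuffer(hist.encode(), dtype=np.uint8) - ord("0")
        first = np.argmax(h, axis=1)
        if n and np.any(h[np.arange(n), first] != 1):
            raise ValidationError("adult_cr: a history has no initial 1")
        last = n_years - 1 - np.argmax(h[:, ::-1], axis=1)
        sex_idx = (adult_cr["sex"].to_numpy() == "m").astype(np.int64)
        age0 = adult_cr["first_age_class"].to_numpy().astype(np.int64)
        if n and (np.any(age0 < 1) or np.any(age0 > 3)):
            raise ValidationError("adult_cr: first_age_class must be 1..3")
        obj = cls(h=h, first=first, last=last, sex_idx=sex_idx, age0=age0,
                  T=n_years)
        obj._prepare()
        return obj

    def _prepare(self):
        n, T = self.h.shape
        t_grid = np.arange(T - 1)[None, :]
        agecls = np.clip(self.age0[:, None] + (t_grid - self.first[:, None]),
                         1, 3)
        # survival over interval t -> t+1 of an age-class-a individual uses
        # s2 for a=1 and s3 for a>=2 (adults were at least 1 year old)
        self.sidx = np.minimum(agecls, 2)
        # m-array sufficient statistics by (sex, age class at release):
        # every sighting is a release in the bird's current age class, so
        # the product of cell probabilities reproduces the individual
        # likelihood exactly.
        self.m_cells = np.zeros((2, 3, T, T))
        self.m_never = np.zeros((2, 3, T))
        for i in range(n):
            seen = np.flatnonzero(self.h[i])
            sx = self.sex_idx[i]
            for a_t, b_t in zip(seen[:-1], seen[1:]):
                acls = min(self.age0[i] + a_t - self.first[i], 3)
                self.m_cells[sx, acls - 1, a_t, b_t] += 1
            acls = min(self.age0[i] + seen[-1] - self.first[i], 3)
            self.m_never[sx, acls - 1, seen[-1]] += 1
        # per-group gather indices for the cell-probability matrices
        r_grid = np.arange(T)[:, None]
        j_grid = np.arange(T)[None, :]
        self._aidx = np.stack([
            np.minimum(np.maximum(a0 + j_grid - r_grid, a0), 2)
            for a0 in (1, 2, 3)])                       # (3, T, T)
        self._jmask = j_grid >= r_grid
        self._upper = (j_grid > r_grid)[None]

    def loglik(self, s: np.ndarray, p: np.ndarray,
               sex: int | None = None) -> float:
        """CJS log-likelihood via the m-array sufficient statistics.

        ``sex`` restricts to one sex's histories (0 = female, 1 = male);
        the two parts are additive.
        """
        n, T = self.h.shape
        if n == 0:
            return 0.0
        ll = 0.0
        j_grid = np.arange(T)[None, None, :]
        upper = self._upper
        # logs are clipped (never -inf) so triangular cumsum differences
        # stay finite; "impossible" cells end up astronomically negative
        for sx in ((0, 1) if sex is None else (sex,)):
            m = self.m_cells[sx]
            nev = self.m_never[sx]
            if m.sum() + nev.sum() == 0:
                continue
            logp = np.log(np.maximum(p[:, sx], 1e-300))
            logq = np.log1p(-np.minimum(p[:, sx], 1 - 1e-16))
            cq = np.cumsum(logq)
            # cell (r, c) needs sum of log(1-p) over j = r+1 .. c-1
            nodet = cq[None, :] - cq[:, None]
            nodet = np.concatenate(
                [np.zeros((T, 1)), nodet[:, :-1]], axis=1)[None]
            S = s[np.broadcast_to(j_grid, (3, T, T)), self._aidx, sx]
            logS = np.where(self._jmask[None],
                            np.log(np.maximum(S, 1e-300)), 0.0)
            cs = np.cumsum(logS, axis=2)
            sumS = np.concatenate(
                [np.zeros((3, T, 1)), cs[:, :, :-1]], axis=2)
            logP = sumS + nodet + logp[None, None, :]
            with np.errstate(over="ignore", under="ignore"):
                chi = 1.0 - np.where(upper, np.exp(logP), 0.0).sum(axis=2)
            chi = np.clip(chi, 1e-300, 1.0)
            ll += float((m * np.where(m > 0, logP, 0.0)).sum())
            ll += float((nev * np.where(nev > 0, np.log(chi), 0.0)).sum())
        return ll

    def loglik_individual(self, s: np.ndarray, p: np.ndarray) -> float:
        n, T = self.h.shape
        if n == 0:
            return 0.0
        PHI = s[np.arange(T - 1)[None, :], self.sidx, self.sex_idx[:, None]]
        P = p[:, self.sex_idx].T                      # (n, T)
        with np.errstate(divide="ignore"):
            logphi = np.log(PHI)
            log1mphi = np.log1p(-PHI)
            logp = np.log(P)
            log1mp = np.log1p(-P)
        # alive-and-detection terms between first and last sighting
        t_grid = np.arange(T - 1)[None, :]
        alive = (t_grid >= self.first[:, None]) & (t_grid < self.last[:, None])
        det = np.where(self.h[:, 1:] == 1, logp[:, 1:], log1mp[:, 1:])
        ll = np.where(alive, logphi + det, 0.0).sum()
        # chi: probability of never being seen again after the last sighting
        chi = np.ones(n)
        chi_at_last = np.where(self.last == T - 1, 1.0, 0.0)
        for t in range(T - 2, -1, -1):
            chi = (1.0 - PHI[:, t]) + PHI[:, t] * (1.0 - P[:, t + 1]) * chi
            chi_at_last = np.where(self.last == t, chi, chi_at_last)
        with np.errstate(divide="ignore"):
            ll += np.where(chi_at_last > 0, np.log(np.maximum(chi_at_last, 1e-300)),
                           _NEG_INF).sum()
        return float(ll)


@dataclass
class RecoveryData:
    """Ring-recovery data aggregated to cohort sufficient statistics.

    ``D[sex, t0, j]`` counts birds ringed as nestlings in year ``t0`` and
    recovered dead in interval ``j`` (0-based: interval ``j`` spans year
    ``t0 + j`` to ``t0 + j + 1``); ``C[sex, t0]`` counts cohort members
    never recovered within the study horizon.
    """

    D: np.ndarray
    C: np.ndarray
    T: int

    @classmethod
    def from_frame(cls, recoveries: pd.DataFrame, n_years: int) -> "RecoveryData":
        D = np.zeros((2, n_years, max(n_years - 1, 1)))
        C = np.zeros((2, n_years))
        for _, row in recoveries.iterrows():
            sx = 1 if row["sex"] == "m" else 0
            t0 = int(row["ring_year"])
            ry = row["recovery_year"]
            if pd.isna(ry) or int(ry) < 0:
                C[sx, t0] += 1
                continue
            ry = int(ry)
            if ry <= t0:
                raise ValidationError(
                    "recoveries: recovery year must exceed ring year")
            D[sx, t0, ry - t0 - 1] += 1
        return cls(D=D, C=C, T=n_years)

    def _indices(self):
        if not hasattr(self, "_yr_c"):
            T = self.T
            K = max(T - 1, 1)
            t0_grid = np.arange(T)[:, None]
            j_grid = np.arange(K)[None, :]
            yr = t0_grid + j_grid              # calendar year of interval j
            self._valid = yr <= T - 2
            self._yr_c = np.minimum(yr, T - 2)
            self._aidx = np.broadcast_to(np.minimum(j_grid, 2), yr.shape)
        return self._yr_c, self._aidx, self._valid

    def interval_logprobs(self, s: np.ndarray, r: np.ndarray):
        """Per-cohort recovery interval probabilities.

        Returns ``(P, Pc)`` where ``P[sex, t0, j]`` is the probability of
        recovery in interval ``j`` and ``Pc[sex, t0]`` the probability of
        never being recovered, for a bird ringed in year ``t0``.
        """
        T = self.T
        K = max(T - 1, 1)
        yr_c, aidx, valid = self._indices()
        P = np.zeros((2, T, K))
        Pc = np.ones((2, T))
        for sx in range(2):
            P[sx] = self._p_matrix(s, r, sx)
            Pc[sx] = 1.0 - P[sx].sum(axis=1)
        return P, Pc

    def _p_matrix(self, s, r, sx):
        yr_c, aidx, valid = self._indices()
        T = self.T
        srv = np.where(valid, s[yr_c, aidx, sx], 1.0)
        cum = np.cumprod(np.concatenate(
            [np.ones((T, 1)), srv[:, :-1]], axis=1), axis=1)
        return np.where(valid, cum * (1.0 - srv) * r[yr_c, sx], 0.0)

    def loglik(self, s: np.ndarray, r: np.ndarray,
               sex: int | None = None) -> float:
        ll = 0.0
        for sx in ((0, 1) if sex is None else (sex,)):
            D, C = self.D[sx], self.C[sx]
            if D.sum() + C.sum() == 0:
                continue
            P = self._p_matrix(s, r, sx)
            if ((D > 0) & (P <= 0)).any():
                return _NEG_INF
            Pc = 1.0 - P.sum(axis=1)
            if ((C > 0) & (Pc <= 0)).any():
                return _NEG_INF
            ll += float(np.where(D > 0,
                                 D * np.log(np.maximum(P, 1e-300)),
                                 0.0).sum())
            ll += float(np.where(C > 0,
                                 C * np.log(np.maximum(Pc, 1e-300)),
                                 0.0).sum())
        return ll


# ---------------------------------------------------------------------------
# public component likelihoods


def loglik_counts(territory_counts, pairs) -> float:
    """Poisson log-likelihood of the annual territory counts.

    ``pairs`` are the latent breeding-pair totals (stage 2+4+5 females).
    """
    obs = np.asarray(territory_counts, dtype=float)
    if np.any(obs < 0):
        raise ValidationError("territory counts must be non-negative")
    return float(log_poisson_pmf(obs, np.asarray(pairs, dtype=float)).sum())


def loglik_breeder_counts(observed, true_counts, p) -> float:
    """Binomial-thinning log-likelihood of the breeder class counts.

    ``observed`` and ``true_counts`` have shape (T, 2, 3): year, sex,
    breeder age class (1-year, 2-year, 3+).  Returns ``-inf`` when more
    breeders were observed than exist in the latent state.
    """
    obs = np.asarray(observed, dtype=float)
    tru = np.asarray(true_counts, dtype=float)
    pp = np.asarray(p, dtype=float)[:, :, None]
    return float(log_binom_pmf(obs, tru, np.broadcast_to(pp, obs.shape)).sum())


def loglik_success(brood_success: pd.DataFrame, eta: np.ndarray) -> float:
    """Bernoulli log-likelihood of the per-brood success indicators."""
    if len(brood_success) == 0:
        return 0.0
    y = brood_success["year"].to_numpy()
    a = brood_success["age_class"].to_numpy() - 1
    k = brood_success["success"].to_numpy().astype(float)
    e = np.asarray(eta, dtype=float)[y, a]
    with np.errstate(divide="ignore"):
        ll = np.where(k == 1, np.log(np.maximum(e, 1e-300)),
                      np.log(np.maximum(1 - e, 1e-300)))
        ll = np.where((k == 1) & (e <= 0), _NEG_INF, ll)
        ll = np.where((k == 0) & (e >= 1), _NEG_INF, ll)
    return float(ll.sum())


def loglik_productivity(brood_fledglings: pd.DataFrame, rho: np.ndarray) -> float:
    """Zero-truncated Poisson log-likelihood of fledgling counts."""
    if len(brood_fledglings) == 0:
        return 0.0
    c = brood_fledglings["count"].to_numpy().astype(float)
    if np.any(c < 1):
        raise ValidationError("successful broods must have >= 1 fledgling")
    y = brood_fledglings["year"].to_numpy()
    a = brood_fledglings["age_class"].to_numpy() - 1
    return float(log_ztpoisson_pmf(c, np.asarray(rho, dtype=float)[y, a]).sum())


def loglik_sexratio(brood_sex: pd.DataFrame, xi: np.ndarray) -> float:
    """Binomial log-likelihood of the brood sex compositions."""
    if len(brood_sex) == 0:
        return 0.0
    y = brood_sex["year"].to_numpy()
    a = brood_sex["age_class"].to_numpy() - 1
    kf = brood_sex["n_female"].to_numpy().astype(float)
    n = kf + brood_sex["n_male"].to_numpy().astype(float)
    return float(log_binom_pmf(kf, n, np.asarray(xi, dtype=float)[y, a]).sum())


def loglik_adult_cr(adult_cr, s: np.ndarray, p: np.ndarray) -> float:
    """Cormack–Jolly–Seber log-likelihood of the adult capture histories."""
    if isinstance(adult_cr, pd.DataFrame):
        adult_cr = CJSData.from_frame(adult_cr, s.shape[0])
    return adult_cr.loglik(s, p)


def loglik_recovery(recoveries, s: np.ndarray, r: np.ndarray) -> float:
    """Seber-style dead-recovery log-likelihood of the ringed nestlings."""
    if isinstance(recoveries, pd.DataFrame):
        recoveries = RecoveryData.from_frame(recoveries, s.shape[0])
    return recoveries.loglik(s, r)


# ---------------------------------------------------------------------------
# latent-state transition density and joint likelihood


@dataclass
class LikelihoodContext:
    """Latent trajectory plus annual demographic and observation rates.

    ``females``/``males`` are the (T, 5) / (T, 6) latent abundances; rate
    arrays follow the module-level shape conventions.
    """

    females: np.ndarray
    males: np.ndarray
    s: np.ndarray
    eta: np.ndarray
    rho: np.ndarray
    xi: np.ndarray
    alpha: np.ndarray
    omega: np.ndarray
    p: np.ndarray
    r: np.ndarray

    @classmethod
    def from_rates(cls, females, males, rates: Sequence[DemographicRatesYear],
                   p, r) -> "LikelihoodContext":
        T = len(rates)
        s = np.stack([rt.s for rt in rates])
        return cls(
            females=np.asarray(females), males=np.asarray(males),
            s=s,
            eta=np.stack([rt.eta for rt in rates]),
            rho=np.stack([rt.rho for rt in rates]),
            xi=np.stack([rt.xi for rt in rates]),
            alpha=np.stack([rt.alpha for rt in rates]),
            omega=np.array([rt.omega for rt in rates]),
            p=np.asarray(p, dtype=float).reshape(T, 2),
            r=np.asarray(r, dtype=float).reshape(T, 2),
        )

    @property
    def n_years(self) -> int:
        return self.females.shape[0]

    def pairs(self) -> np.ndarray:
        return self.females[:, [1, 3, 4]].sum(axis=1)

    def breeder_class_counts(self) -> np.ndarray:
        """True breeder counts by (year, sex, age class): stages 2 / 4 / 5(+6)."""
        T = self.n_years
        out = np.zeros((T, 2, 3))
        out[:, 0, 0] = self.females[:, 1]
        out[:, 0, 1] = self.females[:, 3]
        out[:, 0, 2] = self.females[:, 4]
        out[:, 1, 0] = self.males[:, 1]
        out[:, 1, 1] = self.males[:, 3]
        out[:, 1, 2] = self.males[:, 4] + self.males[:, 5]
        return out


def _production_means(ctx: LikelihoodContext, t: int):
    fb = ctx.females[t, [1, 3, 4]].astype(float)
    per = ctx.eta[t] * ctx.rho[t]
    fem = float(np.sum(fb * per * ctx.xi[t]))
    mal = float(np.sum(fb * per * (1.0 - ctx.xi[t])))
    return fem, mal


def _stage34_marginal_loglik(n1, n2, n3_next, n4_next, s2, a2):
    """Marginal log-probability of next year's (stage 3, stage 4) pair.

    Stage 4 mixes recruits from the stage-1 floaters with surviving
    stage-2 breeders; the split is summed out (small populations, cheap).
    """
    lo = int(max(0, n4_next - n2))
    hi = int(min(n4_next, n1 - n3_next))
    if hi < lo:
        return _NEG_INF
    ks = np.arange(lo, hi + 1)
    terms = (log_trinomial_pmf(n3_next, ks, n1, s2 * (1 - a2), s2 * a2)
             + log_binom_pmf(n4_next - ks, n2, s2))
    return float(logsumexp(terms))


def transition_loglik(ctx: LikelihoodContext) -> float:
    """State-space transition log-density of the latent trajectory."""
    T = ctx.n_years
    ll = 0.0
    F, M = ctx.females, ctx.males
    for t in range(T - 1):
        fem, mal = _production_means(ctx, t)
        a = ctx.alpha[t + 1]
        s = ctx.s[t]
        ll += float(log_poisson_pmf(F[t + 1, 0], fem * s[0, 0] * (1 - a[0, 0])))
        ll += float(log_poisson_pmf(F[t + 1, 1], fem * s[0, 0] * a[0, 0]))
        ll += float(log_poisson_pmf(M[t + 1, 0], mal * s[0, 1] * (1 - a[0, 1])))
        ll += float(log_poisson_pmf(M[t + 1, 1], mal * s[0, 1] * a[0, 1]))
        ll += _stage34_marginal_loglik(F[t, 0], F[t, 1], F[t + 1, 2],
                                       F[t + 1, 3], s[1, 0], a[1, 0])
        ll += _stage34_marginal_loglik(M[t, 0], M[t, 1], M[t + 1, 2],
                                       M[t + 1, 3], s[1, 1], a[1, 1])
        ll += float(log_binom_pmf(F[t + 1, 4], F[t, 2] + F[t, 3] + F[t, 4],
                                  s[2, 0]))
        ll += float(log_binom_pmf(M[t + 1, 4],
                                  M[t, 2] + M[t, 3] + M[t, 4] + M[t, 5],
                                  s[2, 1]))
        ll += float(log_poisson_pmf(M[t + 1, 5], ctx.omega[t + 1]))
        if not np.isfinite(ll):
            return _NEG_INF
    return ll


def joint_loglik(data, ctx: LikelihoodContext) -> float:
    """Joint log-likelihood: the seven components plus the transition density.

    ``data`` is a :class:`~goshawkipm.synthetic_data.MonitoringData`; any
    empty component contributes zero.
    """
    ll = transition_loglik(ctx)
    if not np.isfinite(ll):
        return _NEG_INF
    if len(data.territory_counts):
        ll += loglik_counts(data.territory_counts["count"].to_numpy(),
                            ctx.pairs())
    if len(data.breeder_counts):
        obs = data.breeder_counts_array()
        ll += loglik_breeder_counts(obs, ctx.breeder_class_counts(), ctx.p)
    ll += loglik_success(data.brood_success, ctx.eta)
    ll += loglik_productivity(data.brood_fledglings, ctx.rho)
    ll += loglik_sexratio(data.brood_sex, ctx.xi)
    if len(data.adult_cr):
        ll += loglik_adult_cr(data.adult_cr, ctx.s, ctx.p)
    if len(data.recoveries):
        ll += loglik_recovery(data.recoveries, ctx.s, ctx.r)
    return float(ll)
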