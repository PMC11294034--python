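"""Two-sex stage-structured stochastic projection model.

The model follows a pre-breeding census with three age classes and explicit
breeder / non-breeder stages for each sex:

===== ======================================
stage  meaning
===== ======================================
1      1-year-old non-breeder (floater)
2      1-year-old breeder
3      2-year-old non-breeder
4      2-year-old breeder
5      breeder aged 3 years or more
6      immigrant breeder (males only, the current year's arrivals)
===== ======================================

Only females reproduce in the bookkeeping sense: fledgling production is
driven by the breeding females of stages 2, 4 and 5 through age-specific
breeding success ``eta``, brood size ``rho`` and fledgling sex ratio ``xi``
(proportion of female fledglings).  Fledglings of each sex survive their
first year with sex-specific probability ``s1`` and recruit at age 1 with
probability ``alpha1``; non-recruits enter the floater stage and may recruit
at age 2 with probability ``alpha2``.  From age 3 everybody breeds.  Males
additionally receive a Poisson number of immigrants (expectation ``omega``)
who arrive as breeders aged 3+.

Demographic stochasticity uses Poisson draws for recruitment of new cohorts
and binomial / trinomial draws for survival-and-recruitment transitions, so
survivors can never exceed the pool they are drawn from.  Environmental
stochasticity enters through temporal random effects on the link scale of
every demographic rate (logit for probabilities, identity for brood size,
log for the immigration expectation).

A transition from year ``t`` to ``t + 1`` mixes rates from both years: the
survival and productivity rates are those of year ``t``, while recruitment
probabilities and the immigration expectation are those of year ``t + 1``
(recruitment is decided, and immigrants arrive, in the destination year).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RATE_NAMES",
    "OBS_RATE_NAMES",
    "LINKS",
    "ValidationError",
    "DemographicRatesYear",
    "DemographicHyperParams",
    "PopulationState",
    "Trajectory",
    "link_fn",
    "inv_link_fn",
    "expected_projection_matrix",
    "expected_next_state",
    "stochastic_next_state",
    "expected_trajectory",
    "project_trajectory",
    "annual_growth_rates",
    "geometric_mean_growth",
]

#: demographic rate names on the flat (scalar-per-year) parameterization
RATE_NAMES: tuple[str, ...] = (
    "s1f", "s1m", "s2f", "s2m", "s3f", "s3m",
    "eta1", "eta2", "eta3",
    "rho1", "rho2", "rho3",
    "xi1", "xi2", "xi3",
    "alpha1f", "alpha1m", "alpha2f", "alpha2m",
    "omega",
)

#: observation-process rates (resighting and dead-recovery probabilities)
OBS_RATE_NAMES: tuple[str, ...] = ("pf", "pm", "rf", "rm")

#: link function per rate: logit for probabilities, identity for brood
#: size, log for the immigration expectation
LINKS: dict[str, str] = {name: "logit" for name in RATE_NAMES + OBS_RATE_NAMES}
LINKS.update({"rho1": "identity", "rho2": "identity", "rho3": "identity",
              "omega": "log"})

#: link-scale draws are clamped to this interval before inverse-linking
LINK_CLAMP = 20.0


class ValidationError(ValueError):
    """Raised when states, rates or data violate their invariants."""


def link_fn(name: str, value):
    """Map a rate from its natural scale to its link scale."""
    kind = LINKS[name]
    if kind == "logit":
        # probabilities exactly 0 or 1 map to the clamp boundary rather
        # than +/- infinity
        v = np.clip(np.asarray(value, dtype=float),
                    1.0 / (1.0 + np.exp(LINK_CLAMP)),
                    1.0 / (1.0 + np.exp(-LINK_CLAMP)))
        return np.log(v) - np.log1p(-v)
    if kind == "log":
        return np.log(value)
    return np.asarray(value, dtype=float)


def inv_link_fn(name: str, value):
    """Map a link-scale value back to the natural scale (with clamping)."""
    kind = LINKS[name]
    v = np.clip(np.asarray(value, dtype=float), -LINK_CLAMP, LINK_CLAMP)
    if kind == "logit":
        return 1.0 / (1.0 + np.exp(-v))
    if kind == "log":
        return np.exp(v)
    return v


@dataclass
class DemographicRatesYear:
    """Demographic rates for a single year.

    Attributes
    ----------
    s : (3, 2) array
        Survival by age class (first-year, second-year, adult) and sex
        (column 0 female, column 1 male).
    eta : (3,) array
        Breeding success by maternal age class.
    rho : (3,) array
        Mean fledglings per successful brood by maternal age class.
    xi : (3,) array
        Proportion of female fledglings by maternal age class.
    alpha : (2, 2) array
        Recruitment probability by age (1, 2) and sex.
    omega : float
        Expected number of male immigrants.
    """

    s: np.ndarray
    eta: np.ndarray
    rho: np.ndarray
    xi: np.ndarray
    alpha: np.ndarray
    omega: float

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.omega = float(self.omega)
        self.validate()

    def validate(self) -> None:
        if self.s.shape != (3, 2) or self.alpha.shape != (2, 2):
            raise ValidationError("s must be (3,2) and alpha (2,2)")
        for arr, nm in ((self.s, "s"), (self.eta, "eta"), (self.xi, "xi"),
                        (self.alpha, "alpha")):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValidationError(f"{nm} must lie in [0, 1]")
        if np.any(self.rho < 0):
            raise ValidationError("rho must be non-negative")
        if self.omega < 0:
            raise ValidationError("omega must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicRatesYear":
        """Build from a flat ``{rate name: value}`` mapping."""
        s = np.array([[d["s1f"], d["s1m"]], [d["s2f"], d["s2m"]],
                      [d["s3f"], d["s3m"]]])
        alpha = np.array([[d["alpha1f"], d["alpha1m"]],
                          [d["alpha2f"], d["alpha2m"]]])
        return cls(
            s=s,
            eta=np.array([d["eta1"], d["eta2"], d["eta3"]]),
            rho=np.array([d["rho1"], d["rho2"], d["rho3"]]),
            xi=np.array([d["xi1"], d["xi2"], d["xi3"]]),
            alpha=alpha,
            omega=d["omega"],
        )

    def to_dict(self) -> dict:
        """Flat ``{rate name: value}`` mapping (inverse of :meth:`from_dict`)."""
        d = {}
        for a in range(3):
            d[f"s{a + 1}f"] = float(self.s[a, 0])
            d[f"s{a + 1}m"] = float(self.s[a, 1])
            d[f"eta{a + 1}"] = float(self.eta[a])
            d[f"rho{a + 1}"] = float(self.rho[a])
            d[f"xi{a + 1}"] = float(self.xi[a])
        for a in range(2):
            d[f"alpha{a + 1}f"] = float(self.alpha[a, 0])
            d[f"alpha{a + 1}m"] = float(self.alpha[a, 1])
        d["omega"] = float(self.omega)
        return d


@dataclass
class DemographicHyperParams:
    """Hyperparameters of the temporal random effects on demographic rates.

    ``mu`` and ``sigma`` are keyed by the flat rate names of
    :data:`RATE_NAMES`; both live on the link scale of each rate.
    """

    mu: dict[str, float]
    sigma: dict[str, float]

    def __post_init__(self):
        missing = [n for n in RATE_NAMES if n not in self.mu]
        if missing:
            raise ValidationError(f"missing hyperparameter means: {missing}")
        self.sigma = {n: float(self.sigma.get(n, 0.0)) for n in RATE_NAMES}
        if any(v < 0 for v in self.sigma.values()):
            raise ValidationError("temporal SDs must be non-negative")

    @classmethod
    def from_natural_means(cls, means: dict[str, float],
                           sigmas: dict[str, float] | None = None
                           ) -> "DemographicHyperParams":
        """Build hyperparameters from natural-scale mean rates.

        Means are transformed through each rate's link; ``sigmas`` stay on
        the link scale (default all zero).
        """
        mu = {n: float(link_fn(n, means[n])) for n in RATE_NAMES}
        return cls(mu=mu, sigma=dict(sigmas or {}))

    def mean_rates(self) -> DemographicRatesYear:
        """Rates at the inverse-linked long-term means (no annual deviation)."""
        return DemographicRatesYear.from_dict(
            {n: float(inv_link_fn(n, self.mu[n])) for n in RATE_NAMES})

    def draw_rates(self, years: int, rng: np.random.Generator
                   ) -> list[DemographicRatesYear]:
        """Draw ``years`` annual rate realizations from the random effects."""
        out = []
        for _ in range(years):
            d = {}
            for n in RATE_NAMES:
                z = self.mu[n] + self.sigma[n] * rng.standard_normal()
                v = float(inv_link_fn(n, z))
                if n.startswith("rho"):
                    v = max(v, 0.0)  # identity link can stray negative
                d[n] = v
            out.append(DemographicRatesYear.from_dict(d))
        return out


@dataclass
class PopulationState:
    """Stage-specific abundances for one year (integers).

    ``f`` has 5 female stages, ``m`` has 6 male stages (stage 6 holds the
    current year's immigrants only).
    """

    f: np.ndarray
    m: np.ndarray

    def __post_init__(self):
        self.f = np.asarray(self.f)
        self.m = np.asarray(self.m)
        self.validate()

    def validate(self) -> None:
        if self.f.shape != (5,) or self.m.shape != (6,):
            raise ValidationError("state must have 5 female and 6 male stages")
        if np.any(self.f < 0) or np.any(self.m < 0):
            raise ValidationError("stage abundances must be non-negative")
        if not (np.issubdtype(self.f.dtype, np.integer)
                and np.issubdtype(self.m.dtype, np.integer)):
            raise ValidationError("stage abundances must be integers")

    @property
    def breeding_pairs(self) -> int:
        """Breeding females (stages 2 + 4 + 5): the pair-count summary."""
        return int(self.f[1] + self.f[3] + self.f[4])

    @property
    def total_females(self) -> int:
        return int(self.f.sum())

    @property
    def total(self) -> int:
        return int(self.f.sum() + self.m.sum())

    def as_vector(self) -> np.ndarray:
        """Concatenated (11,) stage vector, females first."""
        return np.concatenate([self.f, self.m]).astype(float)


# ---------------------------------------------------------------------------
# one-step projection


def _production(f_breeders, eta, rho, xi):
    """Expected female and male fledgling production of the breeding females.

    ``f_breeders`` are the stage-2/4/5 female abundances (maternal age
    classes 1, 2, 3+).  Works with float or complex inputs so the expected
    map can be differentiated by complex step.
    """
    per_brood = eta * rho
    fem = np.sum(f_breeders * per_brood * xi)
    male = np.sum(f_breeders * per_brood * (1.0 - xi))
    return fem, male


def expected_projection_matrix(rates: DemographicRatesYear,
                               rates_next: DemographicRatesYear) -> np.ndarray:
    """Expected one-step projection matrix on the 11-stage vector.

    The expected abundances obey ``E[N(t+1)] = M @ N(t) + omega_next * e11``
    (the immigrant stage is the additive constant).  Entries may be complex
    if the input rate arrays are complex (used for complex-step
    sensitivities).
    """
    dtype = np.result_type(rates.s.dtype, rates.eta.dtype, rates.xi.dtype,
                           rates_next.alpha.dtype, float)
    M = np.zeros((11, 11), dtype=dtype)
    fcols = [1, 3, 4]                     # breeding female stages by age class
    per_brood = rates.eta * rates.rho
    for a, c in enumerate(fcols):
        fem = per_brood[a] * rates.xi[a]
        mal = per_brood[a] * (1.0 - rates.xi[a])
        M[0, c] = fem * rates.s[0, 0] * (1.0 - rates_next.alpha[0, 0])
        M[1, c] = fem * rates.s[0, 0] * rates_next.alpha[0, 0]
        M[5, c] = mal * rates.s[0, 1] * (1.0 - rates_next.alpha[0, 1])
        M[6, c] = mal * rates.s[0, 1] * rates_next.alpha[0, 1]
    # female aging / recruitment
    M[2, 0] = rates.s[1, 0] * (1.0 - rates_next.alpha[1, 0])
    M[3, 0] = rates.s[1, 0] * rates_next.alpha[1, 0]
    M[3, 1] = rates.s[1, 0]
    M[4, 2] = M[4, 3] = M[4, 4] = rates.s[2, 0]
    # male aging / recruitment
    M[7, 5] = rates.s[1, 1] * (1.0 - rates_next.alpha[1, 1])
    M[8, 5] = rates.s[1, 1] * rates_next.alpha[1, 1]
    M[8, 6] = rates.s[1, 1]
    M[9, 7] = M[9, 8] = M[9, 9] = M[9, 10] = rates.s[2, 1]
    return M


def expected_next_state(state: PopulationState,
                        rates: DemographicRatesYear,
                        rates_next: DemographicRatesYear) -> np.ndarray:
    """Exact expectation of next year's stage vector.

    Returns the (11,) real-valued vector of Poisson / binomial means,
    females first.  ``rates_next`` supplies the destination-year
    recruitment probabilities and immigration expectation.
    """
    M = expected_projection_matrix(rates, rates_next)
    out = M @ state.as_vector()
    out[10] += rates_next.omega
    return out


def stochastic_next_state(state: PopulationState,
                          rates: DemographicRatesYear,
                          rates_next: DemographicRatesYear,
                          rng: np.random.Generator,
                          size: int | None = None):
    """Draw next year's state from the demographic-stochasticity model.

    With ``size=None`` returns a single :class:`PopulationState`; with an
    integer ``size`` returns ``(F, M)`` integer arrays of shapes
    ``(size, 5)`` and ``(size, 6)`` of independent replicate draws (used
    for Monte-Carlo checks).
    """
    n = 1 if size is None else int(size)
    fb = state.f[[1, 3, 4]].astype(float)
    fem_prod, mal_prod = _production(fb, rates.eta, rates.rho, rates.xi)

    F = np.empty((n, 5), dtype=np.int64)
    M = np.empty((n, 6), dtype=np.int64)
    a1f, a1m = rates_next.alpha[0]
    a2f, a2m = rates_next.alpha[1]
    F[:, 0] = rng.poisson(fem_prod * rates.s[0, 0] * (1 - a1f), size=n)
    F[:, 1] = rng.poisson(fem_prod * rates.s[0, 0] * a1f, size=n)
    M[:, 0] = rng.poisson(mal_prod * rates.s[0, 1] * (1 - a1m), size=n)
    M[:, 1] = rng.poisson(mal_prod * rates.s[0, 1] * a1m, size=n)
    # trinomial split of the 1-year floaters: stay floater / recruit / die
    pf = [rates.s[1, 0] * (1 - a2f), rates.s[1, 0] * a2f]
    pm = [rates.s[1, 1] * (1 - a2m), rates.s[1, 1] * a2m]
    splitf = rng.multinomial(int(state.f[0]), [*pf, 1 - sum(pf)], size=n)
    splitm = rng.multinomial(int(state.m[0]), [*pm, 1 - sum(pm)], size=n)
    F[:, 2] = splitf[:, 0]
    F[:, 3] = splitf[:, 1] + rng.binomial(int(state.f[1]), rates.s[1, 0], size=n)
    M[:, 2] = splitm[:, 0]
    M[:, 3] = splitm[:, 1] + rng.binomial(int(state.m[1]), rates.s[1, 1], size=n)
    F[:, 4] = rng.binomial(int(state.f[2] + state.f[3] + state.f[4]),
                           rates.s[2, 0], size=n)
    M[:, 4] = rng.binomial(int(state.m[2] + state.m[3] + state.m[4] + state.m[5]),
                           rates.s[2, 1], size=n)
    M[:, 5] = rng.poisson(rates_next.omega, size=n)
    if size is None:
        return PopulationState(f=F[0], m=M[0])
    return F, M


# ---------------------------------------------------------------------------
# multi-year projection


@dataclass
class Trajectory:
    """A projected population trajectory with its realized annual rates.

    ``females``/``males`` are ``(T, 5)`` / ``(T, 6)`` abundance arrays
    (float in expected mode); ``rates`` holds one
    :class:`DemographicRatesYear` per year.
    """

    females: np.ndarray
    males: np.ndarray
    rates: list[DemographicRatesYear] = field(repr=False)

    @property
    def years(self) -> int:
        return self.females.shape[0]

    def state(self, t: int) -> PopulationState:
        return PopulationState(f=np.asarray(np.round(self.females[t]), dtype=np.int64),
                               m=np.asarray(np.round(self.males[t]), dtype=np.int64))

    def totals(self, population: str = "females") -> np.ndarray:
        """Per-year population totals under a named definition.

        ``"females"``: all female stages; ``"pairs"``: breeding females
        (stages 2+4+5); ``"all"``: every individual aged >= 1 of both sexes.
        """
        if population == "females":
            return self.females.sum(axis=1)
        if population == "pairs":
            return self.females[:, [1, 3, 4]].sum(axis=1)
        if population == "all":
            return self.females.sum(axis=1) + self.males.sum(axis=1)
        raise ValidationError(f"unknown population definition {population!r}")

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per (year, sex, stage, N)."""
        rows = []
        for t in range(self.years):
            for j in range(5):
                rows.append((t, "f", j + 1, self.females[t, j]))
            for j in range(6):
                rows.append((t, "m", j + 1, self.males[t, j]))
        return pd.DataFrame(rows, columns=["year", "sex", "stage", "N"])

    def rates_frame(self) -> pd.DataFrame:
        """Long table of realized rates: (year, parameter, value)."""
        rows = []
        for t, r in enumerate(self.rates):
            for k, v in r.to_dict().items():
                rows.append((t, k, v))
        return pd.DataFrame(rows, columns=["year", "parameter", "value"])


def expected_trajectory(initial: PopulationState,
                        rates: Sequence[DemographicRatesYear]) -> Trajectory:
    """Propagate expectations (no demographic noise) under given annual rates."""
    T = len(rates)
    if T < 2:
        raise ValidationError("need at least 2 years of rates")
    F = np.zeros((T, 5))
    M = np.zeros((T, 6))
    F[0] = initial.f
    M[0] = initial.m
    vec = initial.as_vector()
    for t in range(T - 1):
        Mt = expected_projection_matrix(rates[t], rates[t + 1])
        vec = Mt @ vec
        vec[10] += rates[t + 1].omega
        F[t + 1] = vec[:5]
        M[t + 1] = vec[5:]
    return Trajectory(females=F, males=M, rates=list(rates))


def project_trajectory(initial: PopulationState,
                       hyper: DemographicHyperParams,
                       years: int,
                       mode: str = "stochastic",
                       seed: int | np.random.Generator | None = None) -> Trajectory:
    """Project the population forward ``years`` years.

    In ``"stochastic"`` mode annual rates are drawn from the temporal
    random effects and states from the Poisson/binomial model; in
    ``"expected"`` mode rates sit at their long-term means and expectations
    are propagated with no sampling of any kind.
    """
    if years < 2:
        raise ValidationError("years must be at least 2")
    if mode not in ("stochastic", "expected"):
        raise ValidationError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    if mode == "expected":
        rates = [hyper.mean_rates() for _ in range(years)]
        return expected_trajectory(initial, rates)
    rates = hyper.draw_rates(years, rng)
    F = np.zeros((years, 5), dtype=np.int64)
    M = np.zeros((years, 6), dtype=np.int64)
    F[0] = initial.f
    M[0] = initial.m
    state = initial
    for t in range(years - 1):
        state = stochastic_next_state(state, rates[t], rates[t + 1], rng)
        F[t + 1] = state.f
        M[t + 1] = state.m
    return Trajectory(females=F, males=M, rates=rates)


def annual_growth_rates(trajectory: Trajectory | np.ndarray,
                        population: str = "females") -> np.ndarray:
    """Realized annual growth rates ``lambda_t = N(t+1) / N(t)``."""
    if isinstance(trajectory, Trajectory):
        totals = trajectory.totals(population)
    else:
        totals = np.asarray(trajectory, dtype=float)
    if np.any(totals <= 0):
        raise ValidationError("population total is zero: growth rate undefined")
    return totals[1:] / totals[:-1]


def geometric_mean_growth(trajectory: Trajectory | np.ndarray,
                          population: str = "females") -> float:
    """Geometric mean of the annual growth rates."""
    lam = annual_growth_rates(trajectory, population)
    return float(np.exp(np.mean(np.log(lam))))
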