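"""Individual-based generator of the seven monitoring data sets.

The generator realizes the two-sex stage-structured model at the level of
individual birds: every fledgling, floater, breeder and immigrant carries
its sex, cohort, annual survival outcomes, recruitment year and per-year
breeding outcomes.  Aggregating the individuals reproduces a valid
stage-abundance trajectory exactly, which makes the generator its own
consistency oracle for the projection model.

A second, independent observation layer thins the complete life histories
into the seven field data sets: territory counts (a noisy census of
breeding pairs), sex/age-class breeder counts and adult capture histories
(annual feather identification with probability ``p`` per sex), per-brood
success / fledgling-count / sex-composition records (a fraction of broods
is monitored), and dead recoveries of ringed nestlings (a fraction of
fledglings is ringed; each death of a ringed bird is reported with
probability ``r``).

The goshawk-like default preset (47 years, ~30-70 pairs, male-biased
fledgling sex ratio, female-biased first-year survival, male-only
immigration) lives in ``presets/goshawk.yaml``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .population_model import (
    DemographicHyperParams,
    DemographicRatesYear,
    PopulationState,
    Trajectory,
    ValidationError,
    inv_link_fn,
    link_fn,
)

__all__ = [
    "ObservationParams",
    "MonitoringData",
    "IndividualHistories",
    "simulate_individuals",
    "observe",
    "simulate_dataset",
    "load_preset",
]

DATA_FILES = (
    "territory_counts.csv", "breeder_counts.csv", "brood_success.csv",
    "brood_fledglings.csv", "brood_sex.csv", "adult_cr.csv",
    "recoveries.csv",
)


@dataclass
class ObservationParams:
    """Parameters of the observation (data-collection) layer.

    ``p`` and ``r`` are the mean annual resighting and dead-recovery
    probabilities per sex (female first); ``sigma_p``/``sigma_r`` put
    temporal random effects on their logit scales.
    """

    p: np.ndarray
    r: np.ndarray
    brood_obs_frac: float = 1.0
    brood_sexed_frac: float = 1.0
    ring_frac: float = 1.0
    sigma_p: float = 0.0
    sigma_r: float = 0.0
    exact_census: bool = False

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        for arr, nm in ((self.p, "p"), (self.r, "r")):
            if arr.shape != (2,) or np.any(arr < 0) or np.any(arr > 1):
                raise ValidationError(f"{nm} must be two probabilities")
        for v, nm in ((self.brood_obs_frac, "brood_obs_frac"),
                      (self.brood_sexed_frac, "brood_sexed_frac"),
                      (self.ring_frac, "ring_frac")):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{nm} must lie in [0, 1]")
        if self.sigma_p < 0 or self.sigma_r < 0:
            raise ValidationError("sigma_p and sigma_r must be >= 0")

    def draw_annual(self, years: int, rng: np.random.Generator):
        """Annual (T, 2) resighting and recovery probabilities."""
        p_t = np.empty((years, 2))
        r_t = np.empty((years, 2))
        for j in range(2):
            zp = link_fn("pf", min(max(self.p[j], 1e-9), 1 - 1e-9))
            zr = link_fn("rf", min(max(self.r[j], 1e-9), 1 - 1e-9))
            p_t[:, j] = inv_link_fn(
                "pf", zp + self.sigma_p * rng.standard_normal(years))
            r_t[:, j] = inv_link_fn(
                "rf", zr + self.sigma_r * rng.standard_normal(years))
            if self.p[j] in (0.0, 1.0) or self.sigma_p == 0:
                p_t[:, j] = self.p[j]
            if self.r[j] in (0.0, 1.0) or self.sigma_r == 0:
                r_t[:, j] = self.r[j]
        return p_t, r_t


@dataclass
class MonitoringData:
    """Container for the seven monitoring data sets.

    Columns: ``territory_counts`` (year, count); ``breeder_counts`` (year,
    sex, age_class, count); ``brood_success`` (year, age_class, success);
    ``brood_fledglings`` (year, age_class, count); ``brood_sex`` (year,
    age_class, n_female, n_male); ``adult_cr`` (id, sex,
    first_age_class, history — a 0/1 string over all years);
    ``recoveries`` (id, sex, ring_year, recovery_year; -1 = censored).
    """

    n_years: int
    territory_counts: pd.DataFrame
    breeder_counts: pd.DataFrame
    brood_success: pd.DataFrame
    brood_fledglings: pd.DataFrame
    brood_sex: pd.DataFrame
    adult_cr: pd.DataFrame
    recoveries: pd.DataFrame

    def validate(self) -> None:
        T = self.n_years
        if (self.territory_counts["count"] < 0).any():
            raise ValidationError("territory_counts: negative count")
        if len(self.brood_fledglings) and (self.brood_fledglings["count"] < 1).any():
            raise ValidationError(
                "brood_fledglings: successful broods need count >= 1")
        if len(self.brood_sex):
            if ((self.brood_sex["n_female"] < 0)
                    | (self.brood_sex["n_male"] < 0)).any():
                raise ValidationError("brood_sex: negative sex counts")
        for _, row in self.recoveries.iterrows():
            ry = row["recovery_year"]
            if ry >= 0 and ry <= row["ring_year"]:
                raise ValidationError(
                    "recoveries: recovery year must exceed ring year")
        for i, h in enumerate(self.adult_cr.get("history", [])):
            h = str(h)
            if len(h) != T or set(h) - {"0", "1"}:
                raise ValidationError(f"adult_cr row {i}: malformed history")
            if "1" not in h:
                raise ValidationError(f"adult_cr row {i}: history has no 1")

    def breeder_counts_array(self) -> np.ndarray:
        """Observed breeder counts as a (T, 2, 3) array (sex f=0, m=1)."""
        out = np.zeros((self.n_years, 2, 3))
        for _, row in self.breeder_counts.iterrows():
            sx = 0 if row["sex"] == "f" else 1
            out[int(row["year"]), sx, int(row["age_class"]) - 1] = row["count"]
        return out

    def m_array(self, sex: str) -> pd.DataFrame:
        """Standard capture-recapture m-array of the adult histories."""
        T = self.n_years
        sub = self.adult_cr[self.adult_cr["sex"] == sex]
        rel = np.zeros(T, dtype=int)
        m = np.zeros((T, T), dtype=int)
        never = np.zeros(T, dtype=int)
        for _, row in sub.iterrows():
            h = str(row["history"])
            seen = [t for t, c in enumerate(h) if c == "1"]
            for a, b in zip(seen[:-1], seen[1:]):
                rel[a] += 1
                m[a, b] += 1
            rel[seen[-1]] += 1
            never[seen[-1]] += 1
        df = pd.DataFrame(m, columns=[f"recap_{t}" for t in range(T)])
        df.insert(0, "released", rel)
        df["never_seen_again"] = never
        return df

    def to_csv_dir(self, out_dir, manifest: dict | None = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frames = (self.territory_counts, self.breeder_counts,
                  self.brood_success, self.brood_fledglings, self.brood_sex,
                  self.adult_cr, self.recoveries)
        for name, df in zip(DATA_FILES, frames):
            df.to_csv(out / name, index=False)
        meta = {"n_years": self.n_years}
        if manifest:
            meta.update(manifest)
        (out / "manifest.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv_dir(cls, in_dir) -> "MonitoringData":
        d = Path(in_dir)
        for name in DATA_FILES + ("manifest.json",):
            if not (d / name).exists():
                raise ValidationError(f"missing data file: {d / name}")
        meta = json.loads((d / "manifest.json").read_text())
        frames = []
        for name in DATA_FILES:
            df = pd.read_csv(d / name, dtype={"history": str})
            frames.append(df)
        obj = cls(meta["n_years"], *frames)
        obj.validate()
        return obj


@dataclass
class IndividualHistories:
    """Complete life histories plus the implied true trajectory and rates."""

    n_years: int
    individuals: pd.DataFrame = field(repr=False)
    broods: pd.DataFrame = field(repr=False)
    stages: dict = field(repr=False)          # id -> {year: stage}
    trajectory: Trajectory = field(repr=False)
    rates: list = field(repr=False)


class _LazyDDRates:
    """Annual rates drawn on first access with a density-dependent mean.

    Rates of year ``t`` are first requested while the simulation is in
    year ``t`` (survival, productivity) or during the transition out of
    year ``t - 1`` (recruitment, immigration of the destination year), so
    the covariate is the exact current female total in the first case and
    lags one year in the second.
    """

    def __init__(self, hyper, betas, center, scale, rng, n_females0):
        from .population_model import RATE_NAMES
        self._names = RATE_NAMES
        self.hyper = hyper
        self.betas = dict(betas)
        self.center = float(center)
        self.scale = float(scale)
        self.rng = rng
        self._x = (n_females0 - self.center) / self.scale
        self._cache: dict[int, DemographicRatesYear] = {}

    def update_covariate(self, n_females: int) -> None:
        self._x = (n_females - self.center) / self.scale

    def __getitem__(self, t: int) -> DemographicRatesYear:
        if t not in self._cache:
            d = {}
            for n in self._names:
                m = self.hyper.mu[n] + self.betas.get(n, 0.0) * self._x
                v = float(inv_link_fn(
                    n, m + self.hyper.sigma[n] * self.rng.standard_normal()))
                if n.startswith("rho"):
                    v = max(v, 0.0)
                d[n] = v
            self._cache[t] = DemographicRatesYear.from_dict(d)
        return self._cache[t]


def _sample_ztpoisson(rng: np.random.Generator, lam: float) -> int:
    """Zero-truncated Poisson draw by inverse cdf on the truncated pmf."""
    if lam <= 0:
        return 1
    u = rng.random() * -np.expm1(-lam)
    c = 0.0
    pk = np.exp(-lam)
    for k in range(1, 200):
        pk = pk * lam / k
        c += pk
        if u <= c:
            return k
    return max(1, int(round(lam)))


def simulate_individuals(hyper: DemographicHyperParams,
                         initial: PopulationState,
                         years: int,
                         seed: int | np.random.Generator | None = None,
                         rates: list[DemographicRatesYear] | None = None,
                         dd_betas: dict | None = None,
                         dd_center: float | None = None,
                         dd_scale: float | None = None
                         ) -> IndividualHistories:
    """Simulate individual life histories under the two-sex stage model.

    Returns every bird that ever fledged, immigrated or was alive at the
    start, its per-year stage occupancy, the brood table of the breeding
    females, the aggregated true trajectory and the realized annual rates.
    If the population of breeding females goes extinct the output is
    truncated (with a warning) at the last year with breeders.

    With ``dd_betas`` the link-scale mean of each listed rate becomes
    ``mu + beta * x_t`` where ``x_t = (N_females,t - dd_center) /
    dd_scale`` is the standardized female total of the running
    population.  Survival and productivity rates of year ``t`` use the
    exact ``x_t``; recruitment and immigration of year ``t + 1`` (needed
    during the transition, before that year's state exists) use ``x_t``
    too, i.e. a one-year lag.
    """
    if years < 2:
        raise ValidationError("years must be at least 2")
    rng = np.random.default_rng(seed)
    if dd_betas:
        if rates is not None:
            raise ValidationError("pass either explicit rates or dd_betas")
        if dd_center is None or dd_scale is None or dd_scale <= 0:
            raise ValidationError("dd_betas needs dd_center and dd_scale > 0")
        rates = _LazyDDRates(hyper, dd_betas, dd_center, dd_scale, rng,
                             initial.total_females)
    elif rates is None:
        rates = hyper.draw_rates(years, rng)
    elif len(rates) != years:
        raise ValidationError("need one DemographicRatesYear per year")

    ind_rows = []          # id, sex, born, origin, death_year
    stages: dict[int, dict[int, int]] = {}
    brood_rows = []
    next_id = [0]

    def new_ind(sex, born, origin):
        i = next_id[0]
        next_id[0] += 1
        ind_rows.append({"id": i, "sex": sex, "born": born,
                         "origin": origin, "death_year": -1})
        return i

    # initial cohort: stage determines age (1, 1, 2, 2, 3, 3)
    alive: dict[int, tuple[str, int, int]] = {}   # id -> (sex, age, stage)
    stage_ages = {1: 1, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3}
    for stage in range(1, 6):
        for _ in range(int(initial.f[stage - 1])):
            i = new_ind("f", -stage_ages[stage], "initial")
            alive[i] = ("f", stage_ages[stage], stage)
    for stage in range(1, 7):
        for _ in range(int(initial.m[stage - 1])):
            i = new_ind("m", -stage_ages[stage], "initial")
            alive[i] = ("m", stage_ages[stage], stage)

    T_eff = years
    fledglings: list[tuple[int, str]] = []     # current year's fledglings
    for t in range(years):
        breeders_f = [(i, a) for i, (sx, a, st) in alive.items()
                      if sx == "f" and st in (2, 4, 5)]
        if not breeders_f and t < years - 1:
            warnings.warn(f"population extinct in year {t}; output truncated")
            T_eff = t
            break
        for i in alive:
            stages.setdefault(i, {})[t] = alive[i][2]
        if isinstance(rates, _LazyDDRates):
            rates.update_covariate(
                sum(1 for sx, _, _ in alive.values() if sx == "f"))
        rt = rates[t]
        # breeding
        fledglings = []
        for i, age in breeders_f:
            a = min(age, 3) - 1
            success = int(rng.random() < rt.eta[a])
            size = nf = nm = 0
            if success:
                size = _sample_ztpoisson(rng, rt.rho[a])
                nf = rng.binomial(size, rt.xi[a])
                nm = size - nf
            brood_rows.append({"year": t, "mother": i, "age_class": a + 1,
                               "success": success, "size": size,
                               "n_female": nf, "n_male": nm})
            for _ in range(nf):
                fledglings.append((new_ind("f", t, "local"), "f"))
            for _ in range(nm):
                fledglings.append((new_ind("m", t, "local"), "m"))
        if t == years - 1:
            break
        rt1 = rates[t + 1]
        new_alive: dict[int, tuple[str, int, int]] = {}
        # fledgling survival and recruitment at age 1
        for i, sx in fledglings:
            j = 0 if sx == "f" else 1
            if rng.random() < rt.s[0, j]:
                st = 2 if rng.random() < rt1.alpha[0, j] else 1
                new_alive[i] = (sx, 1, st)
            else:
                ind_rows[i]["death_year"] = t + 1
        # survival / transition of the standing population
        for i, (sx, age, st) in alive.items():
            j = 0 if sx == "f" else 1
            surv = rt.s[1, j] if age == 1 else rt.s[2, j]
            if rng.random() >= surv:
                ind_rows[i]["death_year"] = t + 1
                continue
            if age == 1:
                if st == 2:
                    nst = 4
                else:
                    nst = 4 if rng.random() < rt1.alpha[1, j] else 3
            else:
                nst = 5
            new_alive[i] = (sx, age + 1, nst)
        # male immigration (arrive as 3+ breeders)
        for _ in range(rng.poisson(rt1.omega)):
            i = new_ind("m", t + 1 - 3, "immigrant")
            new_alive[i] = ("m", 3, 6)
        alive = new_alive

    # aggregate the truth trajectory
    F = np.zeros((T_eff, 5), dtype=np.int64)
    M = np.zeros((T_eff, 6), dtype=np.int64)
    inds = pd.DataFrame(ind_rows)
    for i, sy in stages.items():
        sx = ind_rows[i]["sex"]
        for yy, st in sy.items():
            if yy >= T_eff:
                continue
            if sx == "f":
                F[yy, st - 1] += 1
            else:
                M[yy, st - 1] += 1
    broods = pd.DataFrame(brood_rows)
    if len(broods):
        broods = broods[broods["year"] < T_eff].reset_index(drop=True)
    rates_list = [rates[t] for t in range(T_eff)]
    traj = Trajectory(females=F, males=M, rates=rates_list)
    return IndividualHistories(n_years=T_eff, individuals=inds,
                               broods=broods, stages=stages,
                               trajectory=traj, rates=rates_list)


def observe(hist: IndividualHistories, obs: ObservationParams,
            seed: int | np.random.Generator | None = None) -> MonitoringData:
    """Thin complete life histories into the seven monitoring data sets."""
    rng = np.random.default_rng(seed)
    T = hist.n_years
    p_t, r_t = obs.draw_annual(T, rng)

    pairs = hist.trajectory.females[:, [1, 3, 4]].sum(axis=1)
    if obs.exact_census:
        counts = pairs.astype(int)
    else:
        counts = rng.poisson(pairs)
    territory_counts = pd.DataFrame({"year": np.arange(T), "count": counts})

    # feather identification of breeders
    sex_of = dict(zip(hist.individuals["id"], hist.individuals["sex"]))
    born_of = dict(zip(hist.individuals["id"], hist.individuals["born"]))
    bc = np.zeros((T, 2, 3), dtype=int)
    cr_rows = []
    for i, sy in hist.stages.items():
        sx = sex_of[i]
        jj = 0 if sx == "f" else 1
        det = []
        for yy, st in sorted(sy.items()):
            if yy >= T or st not in (2, 4, 5, 6):
                continue
            if rng.random() < p_t[yy, jj]:
                det.append(yy)
                age_cls = min(yy - born_of[i], 3)
                bc[yy, jj, age_cls - 1] += 1
        if det:
            h = ["0"] * T
            for yy in det:
                h[yy] = "1"
            first = det[0]
            cr_rows.append({"id": i, "sex": sx,
                            "first_age_class": min(first - born_of[i], 3),
                            "history": "".join(h)})
    breeder_counts = pd.DataFrame(
        [{"year": t, "sex": sx, "age_class": a + 1, "count": bc[t, j, a]}
         for t in range(T) for j, sx in enumerate("fm") for a in range(3)])
    adult_cr = pd.DataFrame(cr_rows,
                            columns=["id", "sex", "first_age_class", "history"])

    # brood monitoring
    succ_rows, fled_rows, sex_rows = [], [], []
    for _, b in hist.broods.iterrows():
        if rng.random() >= obs.brood_obs_frac:
            continue
        succ_rows.append({"year": b["year"], "age_class": b["age_class"],
                          "success": b["success"]})
        if b["success"]:
            fled_rows.append({"year": b["year"], "age_class": b["age_class"],
                              "count": b["size"]})
            if rng.random() < obs.brood_sexed_frac:
                sex_rows.append({"year": b["year"],
                                 "age_class": b["age_class"],
                                 "n_female": b["n_female"],
                                 "n_male": b["n_male"]})
    brood_success = pd.DataFrame(succ_rows,
                                 columns=["year", "age_class", "success"])
    brood_fledglings = pd.DataFrame(fled_rows,
                                    columns=["year", "age_class", "count"])
    brood_sex = pd.DataFrame(sex_rows,
                             columns=["year", "age_class", "n_female", "n_male"])

    # nestling ringing and dead recovery
    rec_rows = []
    local = hist.individuals[(hist.individuals["origin"] == "local")
                             & (hist.individuals["born"] < T)]
    for _, row in local.iterrows():
        if rng.random() >= obs.ring_frac:
            continue
        jj = 0 if row["sex"] == "f" else 1
        dy = int(row["death_year"])
        recovered = -1
        if 0 < dy <= T - 1 and rng.random() < r_t[dy - 1, jj]:
            recovered = dy
        rec_rows.append({"id": row["id"], "sex": row["sex"],
                         "ring_year": int(row["born"]),
                         "recovery_year": recovered})
    recoveries = pd.DataFrame(
        rec_rows, columns=["id", "sex", "ring_year", "recovery_year"])

    data = MonitoringData(T, territory_counts, breeder_counts, brood_success,
                          brood_fledglings, brood_sex, adult_cr, recoveries)
    data.validate()
    return data


# ---------------------------------------------------------------------------
# presets


def load_preset(name: str = "goshawk"):
    """Load a versioned study-condition preset.

    Returns ``(hyper, initial, obs, years)``.  ``name`` may also be a path
    to a YAML file with the same schema.
    """
    path = Path(name)
    if path.exists() and path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(path.read_text())
    else:
        ref = resources.files("goshawkipm").joinpath(f"presets/{name}.yaml")
        if not ref.is_file():
            raise ValidationError(f"unknown preset {name!r}")
        cfg = yaml.safe_load(ref.read_text())
    hyper = DemographicHyperParams.from_natural_means(cfg["means"],
                                                      cfg["sigmas"])
    init = PopulationState(
        f=np.asarray(cfg["initial_state"]["females"], dtype=np.int64),
        m=np.asarray(cfg["initial_state"]["males"], dtype=np.int64))
    o = cfg["observation"]
    obs = ObservationParams(
        p=np.array([o["pf"], o["pm"]]), r=np.array([o["rf"], o["rm"]]),
        brood_obs_frac=o["brood_obs_frac"],
        brood_sexed_frac=o.get("brood_sexed_frac", 1.0),
        ring_frac=o["ring_frac"], sigma_p=o["sigma_p"],
        sigma_r=o["sigma_r"], exact_census=o.get("exact_census", False))
    return hyper, init, obs, int(cfg["years"])


def simulate_dataset(preset: str = "goshawk",
                     seed: int | None = 0,
                     years: int | None = None,
                     initial: PopulationState | None = None):
    """End-to-end convenience: preset -> individuals -> observed data.

    Returns ``(data, hist)`` where ``hist`` carries the ground truth.
    """
    hyper, init, obs, T = load_preset(preset)
    if years is not None:
        T = years
    if initial is not None:
        init = initial
    rng = np.random.default_rng(seed)
    hist = simulate_individuals(hyper, init, T, rng)
    data = observe(hist, obs, rng)
    return data, hist
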