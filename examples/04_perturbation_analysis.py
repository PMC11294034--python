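"""Prospective and retrospective analysis of realized population growth.

Runs the transient elasticity, LTRE-contribution and stochasticity
analyses on simulated truth trajectories (no MCMC needed: the analyses
accept any collection of trajectories with known rates).
"""

import numpy as np

import goshawkipm.perturbation as pt
from goshawkipm import project_trajectory
from goshawkipm.inference import PosteriorDraws
from goshawkipm.synthetic_data import load_preset

hyper, initial, _, years = load_preset()
trajs = []
for s in range(30):
    tr = project_trajectory(initial, hyper, years, seed=s)
    if np.all(tr.totals("pairs") > 0):
        trajs.append(tr)
post = PosteriorDraws.from_trajectories(trajs)

el = pt.transient_elasticities(post).table().set_index("component")
lt = pt.ltre_contributions(post)
st = pt.stochasticity_decomposition(post)

print("elasticity of realized growth (top 6):")
print(el["mean"].abs().sort_values(ascending=False).head(6).round(3))
print()
ct = pt.DrawWiseResult(lt.values).table().set_index("component")
print("relative LTRE contributions to var(lambda) (top 6):")
print(ct["mean"].sort_values(ascending=False).head(6).round(3))
print()
print(f"direct (rates) share   : {lt.extras['direct'].mean():.2f}")
print(f"delayed (structure)    : {lt.extras['structure'].mean():.2f}")
print(f"environmental share    : {st.values['env_share'].mean():.2f}")
print()
print("growth responds most strongly to adult survival and to the share")
print("of adult breeders (high elasticities), while among the rates the")
print("most variable one — first-year survival — contributes most to the")
print("year-to-year variance.  On raw simulated trajectories demographic")
print("noise also shakes the realized stage structure, so the structure")
print("contribution here is larger than a fitted-model analysis reports.")
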