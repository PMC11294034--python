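"""Generate the seven monitoring data sets with known ground truth.

The individual-based generator realizes every bird's life history, then
an observation layer thins it into the field data: territory counts,
sex/age-class breeder counts from feather identification, brood success /
size / sex tables, adult capture histories and dead recoveries of ringed
nestlings.
"""

from goshawkipm import simulate_dataset

data, truth = simulate_dataset(seed=1)

print(f"study length: {truth.n_years} years")
print(f"true breeding pairs, first 10 years: "
      f"{truth.trajectory.totals('pairs')[:10].astype(int)}")
print()
print("the seven data sets:")
print(f"  1. territory counts      : {len(data.territory_counts):5d} years")
print(f"  2. breeder class counts  : {len(data.breeder_counts):5d} rows")
print(f"  3. brood success records : {len(data.brood_success):5d} broods")
print(f"  4. fledgling counts      : {len(data.brood_fledglings):5d} broods")
print(f"  5. brood sex counts      : {len(data.brood_sex):5d} broods")
print(f"  6. adult capture histories: {len(data.adult_cr):4d} individuals "
      f"({(data.adult_cr.sex == 'f').sum()} f, "
      f"{(data.adult_cr.sex == 'm').sum()} m)")
n_rec = (data.recoveries.recovery_year >= 0).sum()
print(f"  7. ringed nestlings      : {len(data.recoveries):5d} "
      f"({n_rec} recovered dead)")
print()
print("counts are a noisy census of pairs; every other set is an")
print("incomplete, probabilistic observation of the underlying truth,")
print("which the generator also returns for validation.")
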