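"""Simulate a DHS-like two-stage stratified cluster survey with known truth.

Generates a 30-area lattice, draws an ICAR spatial field and iid area noise,
then samples respondents whose outcome follows
logit p = beta0 + x'beta + f_s(area) + f_u(area).
Because the generating TruthSet is kept, every later stage can be checked
against it.
"""

import numpy as np

from spatialprev import aggregate_to_areas, default_truth, make_lattice_map, simulate_survey

amap = make_lattice_map(5, 6)
truth = default_truth(amap, seed=42)  # beta0=-1, age/education effects, tau_s=2

records = simulate_survey(amap, truth, seed=43)

print(f"{len(records)} respondents in {amap.n_areas} areas, "
      f"{records['psu_id'].nunique()} PSUs, {records['stratum_id'].nunique()} strata")
print(f"overall outcome proportion: {records['outcome'].mean():.3f} "
      f"(truth beta0={truth.beta0} puts the reference pattern at "
      f"{1/(1+np.exp(-truth.beta0)):.3f})")

by_area = records.groupby("area_id")["outcome"].mean()
hot = by_area.idxmax()
print(f"\nhighest-prevalence area {hot}: {by_area[hot]:.2f} "
      f"(its spatial effect f_s = {truth.f_s[amap.index[hot]]:+.2f})")
print(f"spatial field sd across areas: {truth.f_s.std():.2f}")

cases = aggregate_to_areas(records, amap.area_ids)
print(f"\naggregated for scanning: C = {cases.C} cases of N = {cases.N} at risk")
# areas with large positive f_s should show visibly elevated crude prevalence,
# which is exactly the structure the model and the scan are asked to find.
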