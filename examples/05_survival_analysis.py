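"""Survival stratification by cluster and by a single glycoform.

Uses the simulated cohort's exponential survival times (hazard doubles
with each planted cluster index) to show the multigroup log-rank test,
then stratifies patients into Low/Mid/High tertiles of one glycoform's
abundance and tests again.
"""

import pandas as pd

from igpkit.simulate import simulate_cohort
from igpkit.survival import multigroup_logrank, survival_by_group, tertile_stratify

cohort = simulate_cohort(n_tumor=90, n_nat=20, k_clusters=3, n_features=300, seed=13)
tumors = [c for c in cohort.glycoforms.columns if c.startswith("T")]
clin = cohort.clinical.loc[tumors].dropna(subset=["time", "event"]).copy()

# cluster-based stratification
clin["group"] = clin["cluster"].map(lambda c: f"IGP{int(c)}")
chi2, p, df = multigroup_logrank(clin)
print(f"log-rank across planted clusters: chi2 = {chi2:.2f}, df = {df}, p = {p:.3g}")

curves = survival_by_group(clin)
for name, km in sorted(curves.items()):
    print(f"  {name}: S(t=50) = {km.at(50.0):.3f}")

# tertile stratification on one cluster-linked glycoform
feature = cohort.truth.cluster_features[3][0]
values = cohort.glycoforms.loc[feature, tumors]
tert = clin.copy()
tert["group"] = tertile_stratify(values).loc[tert.index]
tert = tert.dropna(subset=["group"])
chi2, p, df = multigroup_logrank(tert)
print(f"\ntertiles of {feature}:")
print(f"log-rank Low/Mid/High: chi2 = {chi2:.2f}, df = {df}, p = {p:.3g}")
# Cluster 3 has the highest planted hazard, so its survival curve sits
# lowest and the cluster-level test is strongly significant.  A single
# glycoform elevated in that cluster carries only part of that signal,
# so its tertile test is noisier and may not reach significance.
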