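"""Glycosylation-phosphorylation crosstalk rewiring between conditions.

Simulates 44 paired tumor/NAT samples where 30 glycoform-phosphosite
pairs are strongly correlated in NAT (r = 0.8) but decoupled in tumors
(r = 0), computes all pairwise within-condition correlations, selects
the rewired pairs (NAT correlation >= 0.3 and a drop > 0.3) and counts
hub proteins on both sides.
"""

from igpkit.crosstalk import hub_counts, paired_condition_correlations, rewired_pairs
from igpkit.simulate import simulate_cohort

cohort = simulate_cohort(
    n_tumor=44, n_nat=44, n_features=100, n_phospho=100,
    n_crosstalk_pairs=30, corr_nat=0.8, corr_tumor=0.0, seed=21,
)
tumors = [c for c in cohort.glycoforms.columns if c.startswith("T")]
nats = [c for c in cohort.glycoforms.columns if c.startswith("N")]

pairs = paired_condition_correlations(
    cohort.glycoforms, cohort.phosphosites, tumors, nats, min_pairs=10
)
selected = rewired_pairs(pairs, delta_threshold=0.3)

truth = cohort.truth.crosstalk_pairs
key = set(zip(selected["glycoform"], selected["phosphosite"]))
hit = sum(1 for g, p in zip(truth["glycoform"], truth["phosphosite"]) if (g, p) in key)

print(f"pairs with both correlations defined : {len(pairs)}")
print(f"rewired pairs selected               : {len(selected)}")
print(f"planted decoupled pairs recovered    : {hit} / {len(truth)}")

glyco_hubs, phospho_hubs = hub_counts(selected)
print("\ntop glyco-side hub genes:")
print(glyco_hubs.head(5).to_string())
print("\ntop phospho-side hub genes:")
print(phospho_hubs.head(5).to_string())
# Selection requires the NAT correlation itself to clear the threshold
# AND the tumor correlation to drop by more than it, so random pairs
# (both correlations near 0) are rarely picked.
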