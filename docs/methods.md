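# Methods

This note documents the models, parameters and numerical choices behind
`igpkit`, and what the synthetic-data experiments do and do not show.

## Glycan model

A composition `NxHyFzSwGv` counts HexNAc (N), Hex (H), fucose/dHex (F),
NeuAc (S) and NeuGc (G) residues. Residue monoisotopic masses are
computed from atomic compositions (HexNAc C8H13NO5, Hex C6H10O5, dHex
C6H10O4, NeuAc C11H17NO8, NeuGc C11H17NO9) through `pyteomics.mass`, so
there is a single source of truth; the glycan's neutral mass is the
residue-mass sum (dehydrated units), which is exactly the mass it adds
on top of a peptide.

Two total classifications operate on compositions:

* **Glycan types** — F≥1 ∧ S≥1 → `F+S`; F≥1 → `only_F`; S≥1 →
  `only_S`; N=2 ∧ 5≤H≤12 ∧ F=S=0 → `HM`; else `Other`. NeuGc does not
  count toward sialylation: the type rules name only fucose and NeuAc,
  so G>0 with F=S=0 and a non-HM backbone is `Other`.
* **Antenna classes** — A = HM; B = non-HM with N≤3; C = 4≤N≤5, S≤1;
  D = 4≤N≤5, S≥2; E = N≥6. HM ⇔ A by construction.

Glycoform keys serialize as `protein_gene_site_composition` and are
parsed by splitting from the right, so protein accessions may contain
underscores as long as the gene symbol does not (a documented
limitation).

## Spectrum preprocessing and search

Preprocessing order: TMT reporter removal (default TMT-11 channels,
±0.003 Da), denoising (top 100 peaks per 100 Th window), deisotoping
(chains spaced 1.00335/z for z up to the precursor charge at 20 ppm,
intensity non-increasing after the second isotope, collapsed onto the
monoisotopic peak with summed intensity). The oxonium screen requires a
HexNAc-oxonium peak in the 10 most intense peaks; the default m/z is
the theoretical 204.0867 (residue + proton) rather than the 204.0966
sometimes printed in workflow descriptions (≈49 ppm from theory), and
is config-exposed because a 20 ppm window around the wrong value would
miss true oxonium ions.

Search proceeds in three stages. (1) The top 300 peaks are matched
against a log-m/z-binned fragment index of singly charged b/y ions;
peptides with more than 6 distinct matched fragments qualify. The index
holds tryptic peptides (cleavage after K/R not before P, ≤2 missed
cleavages, length 6–50) restricted to N-X-S/T sequons, with fixed
carbamidomethyl-C and TMT at the N terminus and K, variable oxidation
of up to 3 M, plus an equal-sized decoy set (interior residues shuffled
with termini fixed, preserving mass and tryptic character; a +11 Da
mass-shift mode exists behind a flag). (2) Qualified candidates are
ranked by the Morpheus score over b/y ions at charges 1–2, the
five-member core Y ladder at all charges up to the precursor charge,
and first isotopes; ties break toward fewer modifications, then
lexicographic sequence. (3) The precursor-minus-peptide gap is searched
in the glycan database at 10 ppm of the precursor mass.

When several glycans fit the gap, diagnostic-ion consistency decides
before mass error: a composition with S>0 (F>0) is preferred only if
NeuAc (HexNAc+Hex+Fuc) oxonium ions are present, and vice versa. This
matters because near-isobaric substitutions exist — 7 Hex and
2 HexNAc + 1 dHex + 2 NeuAc differ by 0.038 Da, within a 10 ppm window
at typical glycopeptide masses — and a pure nearest-mass rule would
misassign a visible fraction of spectra once precursor mass error
(up to 5 ppm in the simulator) is present.

The score bundle reported with each match: OXO score (fraction of
intensity in composition-consistent oxonium ions, with a penalty flag
for inconsistent diagnostics), ISO score (normalized dot product
between the observed MS1 envelope and a 4-isotope theoretical envelope
from averagine statistics plus the glycan's exact atoms under a Poisson
approximation; 0.5 when no envelope is available), Y-ion count and
intensity with a length-dependent QC flag (≥1 core Y ion for peptides
under 15 residues, ≥2 otherwise), and a fucosylation evidence weight.
Only the Morpheus score orders the ranked list; the bundle gates
nothing beyond QC flags.

Target-decoy FDR: PSMs ranked by Morpheus descending; FDR at rank k is
(#decoys)/max(1, #targets) among the top k; q-values are the cumulative
minimum from the bottom; targets with q < 0.01 are retained and decoys
never are. FDR is computed per search run.

## Quantification

Reporter intensities (nearest peak within ±0.003 Da per channel) are
summed across the glycopeptides covering a glycoform *before* any ratio
or log transform (sums of log-ratios would be meaningless); a single
covering glycopeptide passes through unchanged. Values become
log2(channel/pool) and each sample is median-centered; rows with a
missing or zero pool are dropped. Plexes are concatenated after
per-plex normalization with no further batch correction.

## Cohort statistics

* **Differential expression**: two-sided Wilcoxon rank-sum per feature
  (exact when both groups ≤25 without ties, otherwise tie-corrected
  normal approximation), log2 FC = median(A) − median(B) on already-log2
  values, BH adjustment. Categories: FDR<0.01 ∧ log2FC≥1 → S-U; ≤−1 →
  S-D; otherwise U if log2FC>0 else D (zero goes down, an arbitrary
  documented tie rule); everything else NS. Features with <3 non-missing
  values per group are NS with missing p.
* **Over-representation**: one-sided hypergeometric tail with gene sets
  restricted to the user-declared background, BH across sets, default
  significance FDR<0.05.
* **PCA** drops features observed in under half the samples and
  feature-mean imputes the rest, keeping the test path (no imputation)
  decoupled from the ordination.
* **Subtyping**: features with standard deviation above the 25th
  percentile of feature SDs are kept (the alternative literal reading,
  sd > 0.25, is selectable), z-scored, and split into non-negative
  positive/negative halves (exactly invertible). Consensus NMF runs
  scikit-learn's multiplicative-update solver (tol 1e-6, ≤500 updates)
  from seeded random restarts; labels are coefficient argmaxes, the
  consensus matrix is the co-clustering frequency, dispersion is
  (1/n²)Σ4(c−0.5)², and the cophenetic coefficient correlates 1−consensus
  with its average-linkage cophenetic distances (a perfectly binary
  consensus is assigned 1 since the correlation is then degenerate).
  Rank selection maximizes cophenetic×dispersion with ties to the
  smaller rank, then refits; package defaults are ranks 2–10 with
  30 survey and 500 final restarts. Representative features need
  relative basis contribution ≥0.8 (inclusive). Subtype concordance
  uses the Jaccard index with an add-one-smoothed permutation p-value
  and BH across class pairs.
* **Survival**: tertile cutoffs at the 1/3 and 2/3 quantiles with ties
  to the lower group; Kaplan–Meier with Greenwood 95% bands and the
  multigroup log-rank test are delegated to lifelines behind the module
  surface and checked against direct product-limit / O−E oracles in the
  test suite.
* **Crosstalk**: Pearson correlation throughout. Inter-protein pairs
  need ≥10 pairwise-complete observations per condition; rewired pairs
  require corr_NAT ≥ 0.3 *and* corr_NAT − corr_tumor > 0.3 (the
  published "corr > 0.3" criterion is ambiguous; both thresholds are
  config-exposed). Hub counts group selected pairs by gene symbol on
  each side. Enzyme–glycan patterns z-transform glycoform rows,
  aggregate to compositions by median, correlate against enzyme rows
  and cut an average-linkage tree on 1 − correlation-of-profiles into
  k=2 patterns (GC.1/GC.2); the original derivation of those patterns
  is not published, so this hierarchical cut is an explicit substitute.

## Synthetic data

The generators define the study conditions for all tests. Spectra:
fragment intensities are log-normal around a common base; oxonium ions
are placed an order of magnitude above backbone fragments so true scans
pass the screen by construction; reporter ions and Poisson(100·noise)
uniform noise peaks are added; precursor m/z carries up to ±5 ppm
error; confusable noise scans keep the oxonium/reporter signature but
no coherent ladder. Cohorts: baseline log2 values are N(0,1); 10% of
glycoforms are shifted ±2 in tumors (differential truth); per planted
cluster a disjoint 10% block is shifted +2 in that cluster's tumors;
crosstalk pairs are generated as φ = ρ·γ + √(1−ρ²)·ε within each
condition's 44 paired columns (ρ = 0.8 NAT, 0.0 tumor by default);
survival is exponential with the hazard doubling per cluster index and
uniform censoring; missingness is 5% MCAR. These sizes mirror a single
mid-sized tumor/NAT cohort at desk scale.

What passing these tests shows: the pipeline recovers planted structure
under idealized noise — Gaussian effects, MCAR missingness, no batch
effects, no chimeric spectra, no retention-time dimension, no isotope
impurity. It does not show robustness to correlated missingness,
plex-level batch structure, co-eluting precursors or glycan isomerism,
none of which the generators emulate.

## Problem sizes and determinism

The acceptance runs use 40 simulated proteins, 1000 true + 1000 noise
spectra (mixed run) and 500 noise-free spectra; the cohort run uses 100
tumors × 2000 glycoforms with a rank survey over 2–6 at 10 restarts and
a 30-restart refit. These are the package's chosen desk-scale problem
sizes; the survey/refit defaults of the API remain 2–10/30/500. Every
stochastic step takes an explicit seed and regenerates bit-identically;
the CLI writes a manifest (config hash, seed, version) sufficient to
reproduce a run.

One test-design note: the Jaccard permutation statistic is discrete, so
its add-one-smoothed p-values are conservative (super-uniform) rather
than exactly uniform under the null; the suite asserts the operational
guarantee P(p ≤ t) ≲ t rather than a two-sided uniformity test that
discreteness alone would fail.

## Known limitations

Single-sequon site assignment (the first sequon is chosen and ambiguity
flagged, no localization scoring); no open/wildcard glycan search; no
O-glycans, linkage or isomer information; FDR per run rather than
pooled across a cohort; no batch correction beyond per-plex pool
normalization; the exact FlagScore/ISO formulas of the original search
engine are unpublished, so the implementations here are principled
stand-ins documented above.
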