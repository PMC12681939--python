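"""Ground-truth synthetic data generators.

Two families of generators make the whole stack testable without any
external download:

* *spectral*: a random proteome, a glycan composition database, and
  glycopeptide MS/MS spectra with b/y ladders, the five-ion core Y
  ladder, composition-consistent oxonium ions, TMT reporter peaks and
  Poisson-distributed noise peaks — plus confusable noise spectra that
  carry oxonium and reporter ions but no coherent ladder;
* *cohort*: tumor/NAT log2 expression matrices with planted clusters,
  planted differential glycoforms, planted glyco-phospho correlation
  pairs that decouple in tumors, and cluster-linked exponential
  survival.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import PROTON, TMT11_REPORTERS
from .glycans import (
    GlycanComposition,
    GlycanDatabaseEntry,
    classify_antenna_class,
    classify_glycan_type,
)
from .peptides import (
    PeptideEntry,
    apply_modifications,
    sequon_filter,
    tryptic_digest,
)
from .search import CORE_Y_OFFSETS, theoretical_fragments
from .constants import (
    OXONIUM_HEX,
    OXONIUM_HEX2,
    OXONIUM_HEXNAC,
    OXONIUM_HEXNAC_HEX,
    OXONIUM_HEXNAC_HEX_FUC,
    OXONIUM_NEUAC,
    OXONIUM_NEUAC_H2O,
)
from .spectra import FragmentSpectrum

logger = logging.getLogger(__name__)

_AA = "ACDEFGHILMNQSTVWY"  # K/R/P handled explicitly when building peptides


def simulate_proteome(
    n_proteins: int, seed: int, fasta_path=None
) -> dict[str, str]:
    """Random proteins of 200-600 aa built from tryptic blocks.

    Every protein contains at least one tryptic peptide carrying an
    N-X-S/T sequon, so it survives digestion plus sequon filtering.
    Returns accession -> sequence; optionally writes FASTA.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    proteins: dict[str, str] = {}
    for i in range(n_proteins):
        target_len = int(rng.integers(200, 601))
        blocks: list[str] = []
        total = 0
        sequon_planted = False
        while total < target_len:
            blen = int(rng.integers(6, 21))
            body = "".join(rng.choice(list(_AA), size=blen - 1))
            if not sequon_planted and total > 20:
                # embed N-X-S/T (X not P, and not K/R to keep it intra-peptide)
                pos = int(rng.integers(0, blen - 4))
                x = str(rng.choice(list("ACDEFGHILMQVWY")))
                st = str(rng.choice(["S", "T"]))
                body = body[:pos] + "N" + x + st + body[pos + 3 :]
                body = body[: blen - 1]
                sequon_planted = True
            terminal = str(rng.choice(["K", "R"]))
            blocks.append(body + terminal)
            total += blen
        proteins[f"SIMP{i:05d}"] = "".join(blocks)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for acc, seq in proteins.items():
                fh.write(f">{acc} GN={acc.replace('SIMP', 'GENE')}\n")
                for j in range(0, len(seq), 60):
                    fh.write(seq[j : j + 60] + "\n")
    return proteins


def simulate_glycan_db(seed: int, n_extra: int = 30) -> list[GlycanDatabaseEntry]:
    """A glycan composition database covering all five glycan types and
    all five antenna classes (at least 50 compositions)."""
    rng = np.random.default_rng(seed)
    comps: set[GlycanComposition] = set()
    # high-mannose series (type HM / class A)
    for h in range(5, 13):
        comps.add(GlycanComposition(2, h))
    # systematic complex glycans across antenna classes and types
    for n in (2, 3, 4, 5, 6, 7):
        for h in (3, 4, 5, 6, 7):
            for f in (0, 1):
                for s in (0, 1, 2, 3):
                    if len(comps) < 120 and rng.random() < 0.35:
                        comps.add(GlycanComposition(n, h, f, s))
    # make sure every type and class occurs
    comps.update(
        {
            GlycanComposition(3, 4, 1, 0),   # only_F, B
            GlycanComposition(4, 5, 0, 2),   # only_S, D
            GlycanComposition(3, 6, 1, 1),   # F+S, B
            GlycanComposition(4, 5, 1, 1),   # F+S, C
            GlycanComposition(6, 7, 1, 2),   # F+S, E
            GlycanComposition(3, 4, 0, 0),   # Other, B
            GlycanComposition(2, 4, 0, 0, 1),  # Other with NeuGc
        }
    )
    for _ in range(n_extra):
        comps.add(
            GlycanComposition(
                int(rng.integers(2, 8)),
                int(rng.integers(3, 10)),
                int(rng.integers(0, 3)),
                int(rng.integers(0, 4)),
            )
        )
    entries = [GlycanDatabaseEntry.from_composition(c) for c in sorted(comps)]
    types = {classify_glycan_type(e.composition) for e in entries}
    classes = {classify_antenna_class(e.composition) for e in entries}
    assert len(types) == 5 and len(classes) == 5
    return entries


@dataclass
class SpectralTruth:
    """Per-scan ground truth for simulated spectra."""

    table: pd.DataFrame  # scan_id, peptide, glycan, site, charge, is_noise


def _glycan_oxonium_mzs(c: GlycanComposition) -> list[tuple[float, float]]:
    """(m/z, relative intensity weight) of oxonium ions for a composition."""
    ions = [(OXONIUM_HEXNAC, 1.0), (OXONIUM_HEXNAC_HEX, 0.4)]
    if c.n_hex >= 1:
        ions.append((OXONIUM_HEX, 0.3))
    if c.n_hex >= 5:
        ions.append((OXONIUM_HEX2, 0.3))
    if c.n_neuac >= 1:
        ions.extend([(OXONIUM_NEUAC, 0.5), (OXONIUM_NEUAC_H2O, 0.4)])
    if c.n_fuc >= 1:
        ions.append((OXONIUM_HEXNAC_HEX_FUC, 0.3))
    return ions


def simulate_spectra(
    proteins: dict[str, str],
    glycan_db: list[GlycanDatabaseEntry],
    n_true: int,
    n_noise: int,
    noise_level: float,
    seed: int,
) -> tuple[list[FragmentSpectrum], SpectralTruth]:
    """Simulate glycopeptide MS/MS scans plus confusable noise scans.

    True scans contain the full charge-1 b/y ladder of the modified
    peptide, the core Y ladder, composition-consistent oxonium ions
    placed among the most intense peaks, TMT reporter ions and
    ``Poisson(noise_level * 100)`` random noise peaks; the precursor
    m/z carries up to 5 ppm of mass error.  Noise scans share the
    oxonium/reporter signature but have no coherent ladder.
    """
    rng = np.random.default_rng(seed)
    peptides = sequon_filter(tryptic_digest(proteins=proteins))
    if n_true > 0 and not peptides:
        raise ValueError("proteome yields no sequon-containing peptides")
    modified: list[PeptideEntry] = []
    for p in peptides:
        modified.append(apply_modifications(p)[0])  # unoxidised form

    spectra: list[FragmentSpectrum] = []
    rows = []
    base_intensity = 1000.0
    for i in range(n_true):
        p = modified[int(rng.integers(0, len(modified)))]
        g = glycan_db[int(rng.integers(0, len(glycan_db)))]
        charge = int(rng.integers(2, 5))
        igp_mass = p.neutral_mass + g.neutral_mass
        ppm_err = rng.uniform(-5, 5) * 1e-6
        precursor_mz = (igp_mass * (1 + ppm_err) + charge * PROTON) / charge

        mzs: list[float] = []
        ints: list[float] = []
        # peptide backbone: full b/y ladder at charge 1, no isotopes
        for mz in theoretical_fragments(p, precursor_charge=1, with_isotopes=False):
            mzs.append(mz)
            ints.append(base_intensity * rng.lognormal(0.0, 0.4))
        # core Y ladder at charge 1 and 2
        for offset in CORE_Y_OFFSETS:
            for z in (1, 2):
                mzs.append((p.neutral_mass + offset + z * PROTON) / z)
                ints.append(base_intensity * 0.8 * rng.lognormal(0.0, 0.4))
        # oxonium ions, dominating the top of the intensity ranking
        for mz, w in _glycan_oxonium_mzs(g.composition):
            mzs.append(mz)
            ints.append(base_intensity * 10.0 * w * rng.lognormal(0.0, 0.2))
        # TMT reporters
        for mz in TMT11_REPORTERS.values():
            mzs.append(mz)
            ints.append(base_intensity * 5.0 * rng.lognormal(0.0, 0.3))
        # noise
        n_noise_peaks = int(rng.poisson(noise_level * 100))
        for _ in range(n_noise_peaks):
            mzs.append(float(rng.uniform(150.0, max(500.0, precursor_mz))))
            ints.append(base_intensity * 0.5 * rng.lognormal(0.0, 0.8))

        scan_id = f"true{i:06d}"
        spectra.append(
            FragmentSpectrum(scan_id, precursor_mz, charge, np.array(mzs), np.array(ints))
        )
        rows.append(
            {
                "scan_id": scan_id,
                "peptide": p.sequence,
                "glycan": str(g.composition),
                "site": p.protein_sites[0],
                "charge": charge,
                "is_noise": False,
            }
        )

    for i in range(n_noise):
        charge = int(rng.integers(2, 5))
        fake_mass = float(rng.uniform(2500.0, 5500.0))
        precursor_mz = (fake_mass + charge * PROTON) / charge
        mzs, ints = [], []
        for mz, w in [(OXONIUM_HEXNAC, 1.0), (OXONIUM_HEXNAC_HEX, 0.4)]:
            mzs.append(mz)
            ints.append(base_intensity * 10.0 * w * rng.lognormal(0.0, 0.2))
        for mz in TMT11_REPORTERS.values():
            mzs.append(mz)
            ints.append(base_intensity * 5.0 * rng.lognormal(0.0, 0.3))
        for _ in range(max(40, int(rng.poisson(max(noise_level, 1.0) * 100)))):
            mzs.append(float(rng.uniform(150.0, precursor_mz)))
            ints.append(base_intensity * rng.lognormal(0.0, 0.8))
        scan_id = f"noise{i:06d}"
        spectra.append(
            FragmentSpectrum(scan_id, precursor_mz, charge, np.array(mzs), np.array(ints))
        )
        rows.append(
            {
                "scan_id": scan_id,
                "peptide": "",
                "glycan": "",
                "site": 0,
                "charge": charge,
                "is_noise": True,
            }
        )
    truth = SpectralTruth(pd.DataFrame(rows).set_index("scan_id"))
    return spectra, truth


@dataclass
class CohortTruth:
    """Planted structure of a simulated tumor/NAT cohort."""

    clusters: pd.Series                    # tumor sample -> 1..k
    de_features: pd.Series                 # feature -> planted log2 shift
    cluster_features: dict[int, list[str]] = field(default_factory=dict)
    crosstalk_pairs: pd.DataFrame | None = None   # glycoform, phosphosite, corr_nat, corr_tumor
    hazards: dict[int, float] = field(default_factory=dict)
    seed: int = 0


@dataclass
class SimulatedCohort:
    glycoforms: pd.DataFrame
    proteins: pd.DataFrame
    phosphosites: pd.DataFrame
    clinical: pd.DataFrame
    truth: CohortTruth


def _glycoform_keys(n: int, glycan_db: list[GlycanDatabaseEntry], rng) -> list[str]:
    keys = []
    for i in range(n):
        g = glycan_db[int(rng.integers(0, len(glycan_db)))]
        site = int(rng.integers(30, 900))
        keys.append(f"SIMP{i:05d}_GENE{i:05d}_{site}_{g.composition}")
    return keys


def simulate_cohort(
    n_tumor: int = 100,
    n_nat: int = 60,
    k_clusters: int = 3,
    n_features: int = 1000,
    de_fraction: float = 0.1,
    effect_size: float = 2.0,
    cluster_shift: float = 2.0,
    cluster_feature_fraction: float = 0.1,
    n_crosstalk_pairs: int = 50,
    corr_nat: float = 0.8,
    corr_tumor: float = 0.0,
    n_paired: int | None = 44,
    missing_rate: float = 0.05,
    n_phospho: int = 200,
    n_enzymes: int = 0,
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate tumor/NAT cohort matrices with planted structure.

    Baseline log2 values are standard normal.  A ``de_fraction`` of the
    glycoforms is shifted by ±``effect_size`` in all tumors; per
    cluster, a disjoint block of features is shifted by
    ``cluster_shift`` in that cluster's tumors only.  Phosphosites are
    mostly independent noise except the planted crosstalk pairs, whose
    correlation with their partner glycoform is ``corr_nat`` within NAT
    columns and ``corr_tumor`` within tumor columns of the first
    ``n_paired`` patients.  Survival is exponential with a
    cluster-specific hazard; missingness is injected completely at
    random at ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    glycan_db = simulate_glycan_db(seed)
    tumor_samples = [f"T{i:03d}" for i in range(n_tumor)]
    nat_samples = [f"N{i:03d}" for i in range(n_nat)]
    samples = tumor_samples + nat_samples
    features = _glycoform_keys(n_features, glycan_db, rng)

    X = rng.standard_normal((n_features, len(samples)))

    # planted tumor-vs-NAT differential features
    n_de = int(round(de_fraction * n_features))
    de_idx = rng.choice(n_features, size=n_de, replace=False)
    shifts = np.where(rng.random(n_de) < 0.5, effect_size, -effect_size)
    for idx, s in zip(de_idx, shifts):
        X[idx, : n_tumor] += s
    de_features = pd.Series(shifts, index=[features[i] for i in de_idx])

    # planted clusters among tumors
    clusters = pd.Series(
        (rng.permutation(n_tumor) % k_clusters) + 1, index=tumor_samples
    )
    remaining = np.setdiff1d(np.arange(n_features), de_idx)
    n_cf = int(round(cluster_feature_fraction * n_features))
    cluster_features: dict[int, list[str]] = {}
    used = 0
    for c in range(1, k_clusters + 1):
        idx = remaining[used : used + n_cf]
        used += n_cf
        members = [i for i, s in enumerate(tumor_samples) if clusters[s] == c]
        for fi in idx:
            X[fi, members] += cluster_shift
        cluster_features[c] = [features[i] for i in idx]

    glyco = pd.DataFrame(X, index=features, columns=samples)

    # phosphosites: GENE_S<pos> ids; crosstalk pairs planted on paired columns
    phospho_ids = [f"PGENE{i:05d}_S{int(rng.integers(10, 900))}" for i in range(n_phospho)]
    P = rng.standard_normal((n_phospho, len(samples)))
    n_paired = min(n_paired or min(n_tumor, n_nat), n_tumor, n_nat)
    paired_t = tumor_samples[:n_paired]
    paired_n = nat_samples[:n_paired]
    t_cols = [samples.index(s) for s in paired_t]
    n_cols = [samples.index(s) for s in paired_n]
    n_pairs = min(n_crosstalk_pairs, len(remaining) - used, n_phospho)
    pair_glyco_idx = rng.choice(remaining[used:], size=n_pairs, replace=False)
    pair_phos_idx = rng.choice(n_phospho, size=n_pairs, replace=False)
    pair_rows = []
    for gi, pi in zip(pair_glyco_idx, pair_phos_idx):
        for cols, rho in ((n_cols, corr_nat), (t_cols, corr_tumor)):
            eps = rng.standard_normal(len(cols))
            P[pi, cols] = rho * X[gi, cols] + np.sqrt(max(0.0, 1 - rho**2)) * eps
        pair_rows.append(
            {
                "glycoform": features[gi],
                "phosphosite": phospho_ids[pi],
                "corr_nat": corr_nat,
                "corr_tumor": corr_tumor,
            }
        )
    phospho = pd.DataFrame(P, index=phospho_ids, columns=samples)

    # a protein matrix (used e.g. as the enzyme matrix input)
    n_prot = max(n_enzymes, 100)
    prot_ids = [f"PROT{i:05d}" for i in range(n_prot)]
    proteins = pd.DataFrame(
        rng.standard_normal((n_prot, len(samples))), index=prot_ids, columns=samples
    )

    # survival: exponential with cluster-specific hazards
    hazards = {c: 0.01 * (2.0 ** (c - 1)) for c in range(1, k_clusters + 1)}
    times = np.empty(n_tumor)
    events = np.empty(n_tumor, dtype=int)
    for i, s in enumerate(tumor_samples):
        t = rng.exponential(1.0 / hazards[int(clusters[s])])
        censor = rng.uniform(0, 120.0)
        times[i] = min(t, censor)
        events[i] = int(t <= censor)
    clinical = pd.DataFrame(
        {
            "sample": samples,
            "group": ["Tumor"] * n_tumor + ["NAT"] * n_nat,
            "cluster": [int(clusters[s]) for s in tumor_samples] + [np.nan] * n_nat,
            "time": list(times) + [np.nan] * n_nat,
            "event": list(events) + [np.nan] * n_nat,
        }
    ).set_index("sample")

    if missing_rate > 0:
        for M in (glyco, phospho, proteins):
            mask = rng.random(M.shape) < missing_rate
            M.values[mask] = np.nan

    truth = CohortTruth(
        clusters=clusters,
        de_features=de_features,
        cluster_features=cluster_features,
        crosstalk_pairs=pd.DataFrame(pair_rows),
        hazards=hazards,
        seed=seed,
    )
    return SimulatedCohort(glyco, proteins, phospho, clinical, truth)
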