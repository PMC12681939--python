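"""Glycopeptide-spectrum matching.

A spectrum that passes the oxonium screen is matched in three stages:
candidate peptides are fetched from the fragment-ion index (qualified at
more than six distinct fragment matches), ranked by Morpheus score
(matched-fragment count plus matched-intensity fraction) over peptide
b/y ions, core Y ions and their first isotopes; the precursor-minus-
peptide mass gap is then looked up in the glycan database.  Competing
decoy peptides flow through the same path and drive the target-decoy
q-value computation; matches are retained below q = 0.01.
"""

from __future__ import annotations

import logging
import re as _re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import (
    AVERAGINE as _AVERAGINE,
    AVERAGINE_MASS as _AVERAGINE_MASS,
    ISOTOPE_SPACING,
    MONOSACCHARIDE_FORMULAS,
    MONOSACCHARIDE_MASSES,
    OXONIUM_HEX,
    OXONIUM_HEX2,
    OXONIUM_HEXNAC,
    OXONIUM_HEXNAC_HEX,
    OXONIUM_HEXNAC_HEX_FUC,
    OXONIUM_NEUAC,
    OXONIUM_NEUAC_H2O,
    PROTON,
)
from .glycans import GlycanComposition, GlycanDatabaseEntry
from .peptides import FragmentIndex, PeptideEntry, fragment_mzs

logger = logging.getLogger(__name__)

#: Core Y-ion ladder offsets from the peptide mass: pep+HexNAc,
#: pep+2HexNAc, pep+2HexNAc+(1-3)Hex.
_N = MONOSACCHARIDE_MASSES["HexNAc"]
_H = MONOSACCHARIDE_MASSES["Hex"]
CORE_Y_OFFSETS = (_N, 2 * _N, 2 * _N + _H, 2 * _N + 2 * _H, 2 * _N + 3 * _H)


@dataclass
class SearchParams:
    precursor_tol_ppm: float = 10.0
    fragment_tol_ppm: float = 20.0
    fdr_threshold: float = 0.01
    index_top_n: int = 300
    min_fragment_matches: int = 7        # "more than 6"
    #: minimum core-Y matches for the QC flag: short peptides (<15) need 1,
    #: longer need 2.
    yion_qc_short: int = 1
    yion_qc_long: int = 2
    yion_qc_length: int = 15


@dataclass
class ScoreBundle:
    """The score set attached to one glycopeptide-spectrum match."""

    morpheus: float = 0.0
    oxo_score: float = 0.0
    oxo_penalty: bool = False         # inconsistent diagnostics (e.g. NeuAc ions, S=0)
    iso_score: float = 0.5
    yions_count: int = 0
    yions_intensity: float = 0.0
    yions_qc_pass: bool = False
    flag_score: float = 0.0           # fucosylation evidence weight


@dataclass
class GlycoPSM:
    scan_id: str
    peptide: PeptideEntry
    glycan: GlycanDatabaseEntry
    site: int                          # 1-based protein position of chosen sequon
    scores: ScoreBundle
    q_value: float = 1.0
    is_decoy: bool = False
    retained: bool = False
    site_ambiguous: bool = False


def _match_mask(peak_mz: np.ndarray, theoretical: np.ndarray, tol_ppm: float) -> np.ndarray:
    """Boolean mask over peaks lying within tolerance of any theoretical m/z."""
    if len(peak_mz) == 0 or len(theoretical) == 0:
        return np.zeros(len(peak_mz), dtype=bool)
    theoretical = np.sort(theoretical)
    idx = np.searchsorted(theoretical, peak_mz)
    mask = np.zeros(len(peak_mz), dtype=bool)
    tol = peak_mz * tol_ppm * 1e-6
    for shift in (-1, 0):
        j = np.clip(idx + shift, 0, len(theoretical) - 1)
        mask |= np.abs(theoretical[j] - peak_mz) <= tol
    return mask


def _matched_theoretical_count(
    peak_mz: np.ndarray, theoretical: np.ndarray, tol_ppm: float
) -> int:
    """Number of theoretical fragments with at least one matching peak."""
    if len(peak_mz) == 0 or len(theoretical) == 0:
        return 0
    peak_mz = np.sort(peak_mz)
    idx = np.searchsorted(peak_mz, theoretical)
    count = 0
    for t, j in zip(theoretical, idx):
        tol = t * tol_ppm * 1e-6
        for k in (j - 1, j):
            if 0 <= k < len(peak_mz) and abs(peak_mz[k] - t) <= tol:
                count += 1
                break
    return count


def core_y_mzs(pep_mass: float, charges: Sequence[int]) -> np.ndarray:
    """Core Y-ion m/z values over the requested charge states."""
    masses = pep_mass + np.array(CORE_Y_OFFSETS)
    return np.concatenate([(masses + z * PROTON) / z for z in charges])


def theoretical_fragments(
    p: PeptideEntry, precursor_charge: int, with_isotopes: bool = True
) -> np.ndarray:
    """b/y ions (charge 1..min(2,z)), core Y ions (charge 1..z) and,
    optionally, their first isotopes."""
    by_charges = tuple(range(1, min(2, precursor_charge) + 1))
    frags = [fragment_mzs(p, charges=by_charges)]
    y_charges = tuple(range(1, precursor_charge + 1))
    frags.append(core_y_mzs(p.neutral_mass, y_charges))
    base = np.concatenate(frags)
    if with_isotopes:
        # first isotope of every fragment, at each fragment's own charge;
        # approximate with charge-1 and charge-2 spacings
        iso = np.concatenate([base + ISOTOPE_SPACING, base + ISOTOPE_SPACING / 2])
        base = np.concatenate([base, iso])
    return np.sort(base)


def score_morpheus(
    peak_mz: np.ndarray,
    peak_intensity: np.ndarray,
    theoretical: np.ndarray,
    tol_ppm: float = 20.0,
) -> float:
    """Morpheus score: matched theoretical-fragment count plus the
    fraction of total peak intensity carried by matched peaks."""
    total = float(np.sum(peak_intensity))
    if total <= 0 or len(peak_mz) == 0:
        return 0.0
    n_matched = _matched_theoretical_count(peak_mz, theoretical, tol_ppm)
    if n_matched == 0:
        return 0.0
    mask = _match_mask(peak_mz, theoretical, tol_ppm)
    return n_matched + float(np.sum(peak_intensity[mask])) / total


def search_glycan_gap(
    precursor_neutral_mass: float,
    pep_mass: float,
    glycan_db: Sequence[GlycanDatabaseEntry],
    tol_ppm: float = 10.0,
) -> list[GlycanDatabaseEntry]:
    """Glycan database entries whose mass explains the precursor-peptide
    gap within a tolerance scaled by the precursor mass."""
    gap = precursor_neutral_mass - pep_mass
    if gap <= 0:
        return []
    tol = precursor_neutral_mass * tol_ppm * 1e-6
    return [e for e in glycan_db if abs(gap - e.neutral_mass) <= tol]


def score_core_y(
    peak_mz: np.ndarray,
    peak_intensity: np.ndarray,
    pep_mass: float,
    charge: int,
    tol_ppm: float = 20.0,
) -> tuple[int, float]:
    """Count and summed intensity of matched core Y ions (5-ion ladder,
    all charge states up to the precursor charge)."""
    count = 0
    intensity = 0.0
    charges = tuple(range(1, charge + 1))
    for offset in CORE_Y_OFFSETS:
        mzs = np.array([(pep_mass + offset + z * PROTON) / z for z in charges])
        mask = _match_mask(peak_mz, mzs, tol_ppm)
        if mask.any():
            count += 1
            intensity += float(np.sum(peak_intensity[mask]))
    return count, intensity


def score_oxonium(
    peak_mz: np.ndarray,
    peak_intensity: np.ndarray,
    glycan: GlycanComposition,
    tol_ppm: float = 20.0,
) -> tuple[float, bool]:
    """Fraction of total intensity in diagnostic oxonium ions consistent
    with the composition; flags inconsistent diagnostics (NeuAc ions with
    S = 0, fucose ion with F = 0)."""
    total = float(np.sum(peak_intensity))
    if total <= 0:
        return 0.0, False
    expected = [OXONIUM_HEXNAC, OXONIUM_HEXNAC_HEX]
    if glycan.n_hex > 0:
        expected.append(OXONIUM_HEX)
    if glycan.n_hex > 4:
        expected.append(OXONIUM_HEX2)
    if glycan.n_neuac > 0:
        expected.extend([OXONIUM_NEUAC, OXONIUM_NEUAC_H2O])
    if glycan.n_fuc > 0:
        expected.append(OXONIUM_HEXNAC_HEX_FUC)
    mask = _match_mask(peak_mz, np.array(expected), tol_ppm)
    score = float(np.sum(peak_intensity[mask])) / total

    penalty = False
    neuac_mask = _match_mask(peak_mz, np.array([OXONIUM_NEUAC, OXONIUM_NEUAC_H2O]), tol_ppm)
    if glycan.n_neuac == 0 and neuac_mask.any():
        penalty = True
    fuc_mask = _match_mask(peak_mz, np.array([OXONIUM_HEXNAC_HEX_FUC]), tol_ppm)
    if glycan.n_fuc == 0 and fuc_mask.any():
        penalty = True
    return score, penalty


# per-atom heavy-isotope abundances driving the Poisson approximation of
# the aggregated isotope distribution
_ISOTOPE_LAMBDA = {"C": 0.0107, "H": 0.000115, "N": 0.00364, "O": 0.00205, "S": 0.0442}


def _glycan_lambda(glycan: GlycanComposition | None) -> float:
    if glycan is None:
        return 0.0
    counts = {
        "HexNAc": glycan.n_hexnac,
        "Hex": glycan.n_hex,
        "dHex": glycan.n_fuc,
        "NeuAc": glycan.n_neuac,
        "NeuGc": glycan.n_neugc,
    }
    lam = 0.0
    for name, n in counts.items():
        if n == 0:
            continue
        for elem, cnt in _re.findall(r"([A-Z][a-z]?)(\d+)", MONOSACCHARIDE_FORMULAS[name]):
            lam += n * int(cnt) * _ISOTOPE_LAMBDA.get(elem, 0.0)
    return lam


def theoretical_isotope_distribution(
    peptide_mass: float, glycan: GlycanComposition | None = None, n_isotopes: int = 4
) -> np.ndarray:
    """First ``n_isotopes`` relative abundances of the aggregated isotope
    envelope: averagine statistics for the peptide part plus the exact
    atomic composition of the glycan, under a Poisson approximation."""
    lam = peptide_mass / _AVERAGINE_MASS * sum(
        _AVERAGINE[e] * _ISOTOPE_LAMBDA[e] for e in _AVERAGINE
    )
    lam += _glycan_lambda(glycan)
    k = np.arange(n_isotopes)
    from scipy.stats import poisson

    dist = poisson.pmf(k, lam)
    return dist / dist.sum()


def score_isotope(
    ms1_envelope: np.ndarray | None,
    igp_mass: float,
    charge: int,
    glycan: GlycanComposition | None = None,
    tol_ppm: float = 20.0,
) -> float:
    """Normalized dot product between the theoretical isotope envelope of
    the intact glycopeptide and the observed MS1 profile; 0.5 when no
    MS1 envelope is available."""
    if ms1_envelope is None or len(ms1_envelope) == 0:
        return 0.5
    glycan_mass = glycan.mass if glycan is not None else 0.0
    theo = theoretical_isotope_distribution(igp_mass - glycan_mass, glycan)
    mono_mz = (igp_mass + charge * PROTON) / charge
    obs = np.zeros(len(theo))
    env = np.asarray(ms1_envelope, dtype=float)
    for k in range(len(theo)):
        target = mono_mz + k * ISOTOPE_SPACING / charge
        tol = target * tol_ppm * 1e-6
        hit = np.abs(env[:, 0] - target) <= tol
        if hit.any():
            obs[k] = env[hit, 1].sum()
    denom = np.linalg.norm(theo) * np.linalg.norm(obs)
    if denom == 0:
        return 0.0
    return float(np.dot(theo, obs) / denom)


def search_spectrum(
    spectrum,
    index: FragmentIndex,
    glycan_db: Sequence[GlycanDatabaseEntry],
    params: SearchParams | None = None,
) -> GlycoPSM | None:
    """Match one preprocessed, oxonium-positive spectrum.

    Returns the best glycopeptide-spectrum match or None when no peptide
    qualifies or the mass gap matches no glycan.
    """
    params = params or SearchParams()
    candidates = index.query(
        spectrum.mz,
        spectrum.intensity,
        top_n=params.index_top_n,
        min_matches=params.min_fragment_matches,
    )
    if not candidates:
        return None
    scored: list[tuple[float, PeptideEntry]] = []
    for pep_idx in candidates:
        p = index.peptides[pep_idx]
        theo = theoretical_fragments(p, spectrum.precursor_charge)
        m = score_morpheus(spectrum.mz, spectrum.intensity, theo, params.fragment_tol_ppm)
        scored.append((m, p))
    # ties: fewer modifications, then lexicographic sequence (deterministic)
    scored.sort(key=lambda t: (-t[0], len(t[1].modifications), t[1].sequence))
    morpheus, best = scored[0]
    if morpheus <= 0:
        return None

    glycans = search_glycan_gap(
        spectrum.precursor_neutral_mass,
        best.neutral_mass,
        glycan_db,
        tol_ppm=params.precursor_tol_ppm,
    )
    if not glycans:
        logger.debug("scan %s: peptide %s matched but gap not in glycan db",
                     spectrum.scan_id, best.sequence)
        return None
    gap = spectrum.precursor_neutral_mass - best.neutral_mass
    # near-isobaric compositions (e.g. 7 Hex vs 2 HexNAc + Fuc + 2 NeuAc,
    # 0.038 Da apart) are disambiguated by diagnostic-ion consistency
    # before mass error
    has_neuac = _match_mask(
        spectrum.mz, np.array([OXONIUM_NEUAC, OXONIUM_NEUAC_H2O]), params.fragment_tol_ppm
    ).any()
    has_fuc = _match_mask(
        spectrum.mz, np.array([OXONIUM_HEXNAC_HEX_FUC]), params.fragment_tol_ppm
    ).any()

    def _inconsistency(e: GlycanDatabaseEntry) -> int:
        c = e.composition
        return int((c.n_neuac > 0) != has_neuac) + int((c.n_fuc > 0) != has_fuc)

    glycan = min(glycans, key=lambda e: (_inconsistency(e), abs(gap - e.neutral_mass)))

    y_count, y_intensity = score_core_y(
        spectrum.mz, spectrum.intensity, best.neutral_mass,
        spectrum.precursor_charge, params.fragment_tol_ppm,
    )
    qc_min = (
        params.yion_qc_short
        if len(best.sequence) < params.yion_qc_length
        else params.yion_qc_long
    )
    oxo, penalty = score_oxonium(
        spectrum.mz, spectrum.intensity, glycan.composition, params.fragment_tol_ppm
    )
    iso = score_isotope(
        spectrum.ms1_envelope,
        best.neutral_mass + glycan.neutral_mass,
        spectrum.precursor_charge,
        glycan.composition,
        params.fragment_tol_ppm,
    )
    flag = 0.0
    if glycan.composition.n_fuc >= 1:
        fuc_y = (best.neutral_mass + _N + MONOSACCHARIDE_MASSES["dHex"] + PROTON)
        has_fuc_y = _match_mask(spectrum.mz, np.array([fuc_y]), params.fragment_tol_ppm).any()
        has_fuc_oxo = _match_mask(
            spectrum.mz, np.array([OXONIUM_HEXNAC_HEX_FUC]), params.fragment_tol_ppm
        ).any()
        flag = float(has_fuc_y) + float(has_fuc_oxo)

    site = best.protein_sites[0] if best.protein_sites else 0
    bundle = ScoreBundle(
        morpheus=morpheus,
        oxo_score=oxo,
        oxo_penalty=penalty,
        iso_score=iso,
        yions_count=y_count,
        yions_intensity=y_intensity,
        yions_qc_pass=y_count >= qc_min,
        flag_score=flag,
    )
    return GlycoPSM(
        scan_id=spectrum.scan_id,
        peptide=best,
        glycan=glycan,
        site=site,
        scores=bundle,
        is_decoy=best.is_decoy,
        site_ambiguous=len(best.protein_sites) > 1,
    )


def target_decoy_fdr(
    psms: Sequence[GlycoPSM], threshold: float = 0.01
) -> list[GlycoPSM]:
    """Assign q-values by the target-decoy method and mark retained PSMs.

    PSMs are ranked by Morpheus score descending; FDR at rank k is
    decoys/max(1, targets) in the top k; q-values are the cumulative
    minimum from the bottom.  Decoys are never retained.
    """
    ranked = sorted(
        psms,
        key=lambda p: (
            -p.scores.morpheus,
            len(p.peptide.modifications),
            p.peptide.sequence,
        ),
    )
    n_decoy = 0
    n_target = 0
    fdrs = []
    for p in ranked:
        if p.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        fdrs.append(n_decoy / max(1, n_target))
    q = 1.0
    for i in range(len(ranked) - 1, -1, -1):
        q = min(q, fdrs[i])
        ranked[i].q_value = q
        ranked[i].retained = (not ranked[i].is_decoy) and q < threshold
    return ranked


def psms_to_table(psms: Sequence[GlycoPSM]):
    """Flatten PSMs into a pandas DataFrame (one row per PSM)."""
    import pandas as pd

    rows = []
    for p in psms:
        rows.append(
            {
                "scan": p.scan_id,
                "peptide": p.peptide.sequence,
                "modifications": ";".join(
                    f"{pos}:{delta:.6f}" for pos, delta in p.peptide.modifications
                ),
                "protein": p.peptide.protein_ids[0],
                "gene": p.peptide.genes[0],
                "site": p.site,
                "glycan": str(p.glycan.composition),
                "morpheus": p.scores.morpheus,
                "oxo_score": p.scores.oxo_score,
                "iso_score": p.scores.iso_score,
                "yions_count": p.scores.yions_count,
                "yions_intensity": p.scores.yions_intensity,
                "flag_score": p.scores.flag_score,
                "q_value": p.q_value,
                "is_decoy": p.is_decoy,
                "retained": p.retained,
            }
        )
    return pd.DataFrame(rows)
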