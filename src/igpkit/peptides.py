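"""In-silico digestion, sequon filtering, modifications, decoys, and the
fragment-ion index used for peptide-backbone candidate lookup.

The search database consists of deglycosylated tryptic peptides carrying
at least one N-X-S/T sequon (X != P).  Fixed modifications are
carbamidomethyl-C and a TMT label at the peptide N terminus and on every
K; oxidised M is variable.  An equal-sized decoy set (interior-shuffled,
mass-preserving) is searched in parallel for FDR estimation.
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass, field, replace
from math import log
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import fasta as _fasta
from pyteomics.mass import std_aa_mass

from .constants import MOD_CARBAMIDOMETHYL, MOD_OXIDATION, MOD_TMT, PROTON, WATER

logger = logging.getLogger(__name__)

_SEQUON_RE = re.compile(r"N(?=[^P][ST])")
_CLEAVE_RE = re.compile(r"(?<=[KR])(?!P)")
NTERM = -1  # modification position marker for the peptide N terminus


@dataclass
class PeptideEntry:
    """A (possibly modified) peptide from the digest database."""

    sequence: str
    protein_ids: tuple[str, ...]
    genes: tuple[str, ...]
    sequon_offsets: tuple[int, ...]       # 0-based peptide positions of sequon N
    protein_sites: tuple[int, ...]        # 1-based protein positions, parallel
    n_missed: int
    modifications: tuple[tuple[int, float], ...] = ()  # (position, delta Da); NTERM=-1
    neutral_mass: float = 0.0
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence or not self.sequence.isupper():
            raise ValueError(f"invalid peptide sequence {self.sequence!r}")


def find_sequons(sequence: str) -> list[int]:
    """0-based offsets of N in N-X-S/T (X != P) within a peptide."""
    return [m.start() for m in _SEQUON_RE.finditer(sequence)]


def _digest_sequence(seq: str, max_missed: int, min_len: int, max_len: int):
    """Yield (peptide, start_0based, n_missed) for a tryptic digest."""
    pieces = [p for p in _CLEAVE_RE.split(seq) if p]
    starts = []
    pos = 0
    for p in pieces:
        starts.append(pos)
        pos += len(p)
    for i in range(len(pieces)):
        for m in range(max_missed + 1):
            if i + m >= len(pieces):
                break
            pep = "".join(pieces[i : i + m + 1])
            if min_len <= len(pep) <= max_len:
                yield pep, starts[i], m


def tryptic_digest(
    fasta_path: str | Path | None = None,
    *,
    proteins: dict[str, str] | None = None,
    genes: dict[str, str] | None = None,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 50,
) -> list[PeptideEntry]:
    """Digest a FASTA (or an in-memory accession->sequence dict).

    Cleaves after K/R except before P, allowing up to ``max_missed``
    missed cleavages; peptides of length 6-50 are retained and shared
    peptides are merged across proteins.  Gene symbols are taken from a
    ``GN=`` token in the FASTA description when present.
    """
    if proteins is None:
        proteins = {}
        genes = dict(genes or {})
        for header, seq in _fasta.read(str(fasta_path)):
            accession = header.split()[0]
            m = re.search(r"\bGN=(\S+)", header)
            genes[accession] = m.group(1) if m else accession
            proteins[accession] = seq.upper()
    else:
        genes = dict(genes or {acc: acc for acc in proteins})
    if not proteins:
        logger.warning("empty protein database from %s", fasta_path)
        return []

    merged: dict[tuple[str, int], PeptideEntry] = {}
    for accession, seq in proteins.items():
        gene = genes.get(accession, accession)
        for pep, start, n_missed in _digest_sequence(seq, max_missed, min_len, max_len):
            offsets = tuple(find_sequons(pep))
            sites = tuple(start + o + 1 for o in offsets)
            key = (pep, n_missed)
            if key in merged:
                e = merged[key]
                if accession not in e.protein_ids:
                    merged[key] = replace(
                        e,
                        protein_ids=e.protein_ids + (accession,),
                        genes=e.genes + (gene,),
                    )
            else:
                merged[key] = PeptideEntry(
                    sequence=pep,
                    protein_ids=(accession,),
                    genes=(gene,),
                    sequon_offsets=offsets,
                    protein_sites=sites,
                    n_missed=n_missed,
                    neutral_mass=peptide_mass_unmodified(pep),
                )
    return list(merged.values())


def sequon_filter(peptides: Iterable[PeptideEntry]) -> list[PeptideEntry]:
    """Retain only peptides containing at least one N-X-S/T sequon."""
    return [p for p in peptides if p.sequon_offsets]


def peptide_mass_unmodified(sequence: str) -> float:
    """Monoisotopic residue sum plus water for an unmodified peptide."""
    try:
        return sum(std_aa_mass[a] for a in sequence) + WATER
    except KeyError as exc:
        raise ValueError(f"unknown amino-acid residue {exc.args[0]!r} in {sequence!r}") from None


def peptide_mass(p: PeptideEntry) -> float:
    """Neutral monoisotopic mass including modification deltas."""
    return peptide_mass_unmodified(p.sequence) + sum(d for _, d in p.modifications)


def apply_modifications(p: PeptideEntry, max_variable: int = 3) -> list[PeptideEntry]:
    """Expand a peptide into its modified forms.

    Fixed: carbamidomethyl on every C, TMT on the N terminus and every
    K.  Variable: oxidation on M, one entry per combination (capped at
    ``max_variable`` simultaneous oxidations).
    """
    fixed: list[tuple[int, float]] = [(NTERM, MOD_TMT)]
    for i, aa in enumerate(p.sequence):
        if aa == "C":
            fixed.append((i, MOD_CARBAMIDOMETHYL))
        elif aa == "K":
            fixed.append((i, MOD_TMT))
    m_positions = [i for i, aa in enumerate(p.sequence) if aa == "M"]

    out: list[PeptideEntry] = []
    from itertools import combinations

    variants: list[tuple[int, ...]] = [()]
    for r in range(1, min(len(m_positions), max_variable) + 1):
        variants.extend(combinations(m_positions, r))
    for var in variants:
        mods = tuple(sorted(fixed + [(i, MOD_OXIDATION) for i in var]))
        entry = replace(p, modifications=mods)
        entry.neutral_mass = peptide_mass(entry)
        out.append(entry)
    return out


def generate_decoys(
    peptides: Sequence[PeptideEntry], seed: int, mode: str = "shuffle"
) -> list[PeptideEntry]:
    """One decoy per target peptide; deterministic under ``seed``.

    ``shuffle`` (default) shuffles interior residues, preserving both
    termini and hence the tryptic character and the exact mass; the
    decoy keeps pseudo-sequon positions so it traverses the same search
    path.  ``mass_shift`` instead offsets the neutral mass by +11 Da.
    """
    rng = random.Random(seed)
    decoys: list[PeptideEntry] = []
    for p in peptides:
        if mode == "shuffle":
            seq = p.sequence
            if len(seq) > 3:
                interior = list(seq[1:-1])
                rng.shuffle(interior)
                seq = seq[0] + "".join(interior) + seq[-1]
            offsets = tuple(min(o, len(seq) - 3) for o in p.sequon_offsets)
            d = replace(
                p,
                sequence=seq,
                sequon_offsets=offsets,
                protein_ids=tuple("DECOY_" + a for a in p.protein_ids),
                genes=tuple("DECOY_" + g for g in p.genes),
                is_decoy=True,
            )
            d.neutral_mass = peptide_mass_unmodified(seq)
        elif mode == "mass_shift":
            d = replace(
                p,
                protein_ids=tuple("DECOY_" + a for a in p.protein_ids),
                genes=tuple("DECOY_" + g for g in p.genes),
                is_decoy=True,
                neutral_mass=p.neutral_mass + 11.0,
            )
        else:
            raise ValueError(f"unknown decoy mode {mode!r}")
        decoys.append(d)
    return decoys


def residue_masses(p: PeptideEntry) -> np.ndarray:
    """Per-residue masses including modification deltas (N-term on residue 0)."""
    masses = np.array([std_aa_mass[a] for a in p.sequence], dtype=float)
    for pos, delta in p.modifications:
        masses[max(pos, 0)] += delta
    return masses


def fragment_mzs(p: PeptideEntry, charges: Sequence[int] = (1,)) -> np.ndarray:
    """Theoretical b/y ion m/z values at the given charges, sorted."""
    masses = residue_masses(p)
    prefix = np.cumsum(masses)[:-1]            # b fragments (residue sums)
    suffix = np.cumsum(masses[::-1])[:-1]      # y fragments
    out = []
    for z in charges:
        out.append((prefix + z * PROTON) / z)
        out.append((suffix + WATER + z * PROTON) / z)
    return np.sort(np.concatenate(out)) if out else np.array([])


class FragmentIndex:
    """Inverted index from fragment m/z to peptides.

    Bins are uniform in log(m/z) with width equal to the fragment
    tolerance, so any peak within tolerance of a fragment lies in the
    same or an adjacent bin; candidate hits are then verified at the
    exact ppm tolerance.
    """

    def __init__(self, peptides: Sequence[PeptideEntry], tol_ppm: float = 20.0):
        self.peptides = list(peptides)
        self.tol_ppm = tol_ppm
        self._bin_width = tol_ppm * 1e-6
        self.bins: dict[int, list[tuple[float, int, int]]] = {}
        for pep_idx, p in enumerate(self.peptides):
            for frag_id, mz in enumerate(fragment_mzs(p, charges=(1,))):
                self.bins.setdefault(self._bin_of(mz), []).append((mz, pep_idx, frag_id))

    def _bin_of(self, mz: float) -> int:
        return int(log(mz) / self._bin_width)

    def query(
        self,
        mz: np.ndarray,
        intensity: np.ndarray,
        top_n: int = 300,
        min_matches: int = 7,
    ) -> dict[int, int]:
        """Match the top-N peaks against the index.

        Returns ``{peptide index: matched-fragment count}`` for peptides
        reaching ``min_matches`` distinct fragment matches (the default
        requires more than 6).
        """
        mz = np.asarray(mz, dtype=float)
        if len(mz) > top_n:
            keep = np.argsort(np.asarray(intensity))[-top_n:]
            mz = mz[keep]
        matched: dict[int, set[int]] = {}
        for peak_mz in mz:
            if peak_mz <= 0:
                continue
            b = self._bin_of(peak_mz)
            tol = peak_mz * self.tol_ppm * 1e-6
            for bb in (b - 1, b, b + 1):
                for frag_mz, pep_idx, frag_id in self.bins.get(bb, ()):
                    if abs(frag_mz - peak_mz) <= tol:
                        matched.setdefault(pep_idx, set()).add(frag_id)
        return {
            idx: len(frags) for idx, frags in matched.items() if len(frags) >= min_matches
        }


def build_search_database(
    fasta_path: str | Path | None = None,
    *,
    proteins: dict[str, str] | None = None,
    genes: dict[str, str] | None = None,
    decoy_seed: int = 0,
    max_missed: int = 2,
    tol_ppm: float = 20.0,
) -> FragmentIndex:
    """Digest, sequon-filter, add decoys, modify, and index."""
    targets = sequon_filter(
        tryptic_digest(fasta_path, proteins=proteins, genes=genes, max_missed=max_missed)
    )
    decoys = generate_decoys(targets, seed=decoy_seed)
    entries: list[PeptideEntry] = []
    for p in list(targets) + decoys:
        entries.extend(apply_modifications(p))
    logger.info(
        "search database: %d target peptides, %d decoys, %d modified forms",
        len(targets), len(decoys), len(entries),
    )
    return FragmentIndex(entries, tol_ppm=tol_ppm)
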