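"""Glycan composition parsing, mass computation and classification.

An N-glycan composition is written ``NxHyFzSwGv``: x HexNAc, y Hex,
z fucose (dHex), w NeuAc and v NeuGc residues.  Two classification
schemes operate on compositions:

* five glycan *types* — high mannose (HM), fucosylated only (only_F),
  sialylated only (only_S), fucosylated and sialylated (F+S), Other;
* five *antenna classes* A–E using the HexNAc count as a proxy for
  branching and the NeuAc count for terminal capping.

Glycoforms are keyed by ``protein_gene_site_composition``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .constants import MONOSACCHARIDE_MASSES

logger = logging.getLogger(__name__)

_COMPOSITION_RE = re.compile(r"^N(\d+)H(\d+)F(\d+)S(\d+)G(\d+)$")

GLYCAN_TYPES = ("HM", "only_F", "only_S", "F+S", "Other")
ANTENNA_CLASSES = ("A", "B", "C", "D", "E")


class GlycanParseError(ValueError):
    """Raised when a composition or glycoform key cannot be parsed."""


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Counts of the five monosaccharide classes of an N-glycan.

    Attributes
    ----------
    n_hexnac, n_hex, n_fuc, n_neuac, n_neugc :
        Non-negative residue counts (the N, H, F, S, G of the string form).
    """

    n_hexnac: int
    n_hex: int
    n_fuc: int = 0
    n_neuac: int = 0
    n_neugc: int = 0

    def __post_init__(self) -> None:
        for field in ("n_hexnac", "n_hex", "n_fuc", "n_neuac", "n_neugc"):
            v = getattr(self, field)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{field} must be a non-negative integer, got {v!r}")

    def __str__(self) -> str:
        return (
            f"N{self.n_hexnac}H{self.n_hex}F{self.n_fuc}"
            f"S{self.n_neuac}G{self.n_neugc}"
        )

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.n_hexnac + other.n_hexnac,
            self.n_hex + other.n_hex,
            self.n_fuc + other.n_fuc,
            self.n_neuac + other.n_neuac,
            self.n_neugc + other.n_neugc,
        )

    @property
    def mass(self) -> float:
        return composition_mass(self)


def parse_composition(text: str) -> GlycanComposition:
    """Parse a ``NxHyFzSwGv`` string into a :class:`GlycanComposition`."""
    m = _COMPOSITION_RE.match(text.strip())
    if m is None:
        raise GlycanParseError(
            f"malformed glycan composition {text!r}: expected N<int>H<int>F<int>S<int>G<int>"
        )
    return GlycanComposition(*(int(g) for g in m.groups()))


def composition_mass(c: GlycanComposition) -> float:
    """Monoisotopic neutral mass of the glycan residues, in Da.

    The glycan contributes residue masses only (dehydrated units), which
    is the mass gap it adds on top of the peptide.
    """
    return (
        c.n_hexnac * MONOSACCHARIDE_MASSES["HexNAc"]
        + c.n_hex * MONOSACCHARIDE_MASSES["Hex"]
        + c.n_fuc * MONOSACCHARIDE_MASSES["dHex"]
        + c.n_neuac * MONOSACCHARIDE_MASSES["NeuAc"]
        + c.n_neugc * MONOSACCHARIDE_MASSES["NeuGc"]
    )


def is_high_mannose(c: GlycanComposition) -> bool:
    """High mannose: N = 2, 5 <= H <= 12, no fucose, no NeuAc."""
    return c.n_hexnac == 2 and 5 <= c.n_hex <= 12 and c.n_fuc == 0 and c.n_neuac == 0


def classify_glycan_type(c: GlycanComposition) -> str:
    """Assign one of the five glycan types.

    Fucose/NeuAc presence decides F+S / only_F / only_S; high-mannose
    compositions (which have neither) form HM; everything else is Other.
    NeuGc does not count as sialylation here.
    """
    if c.n_fuc >= 1 and c.n_neuac >= 1:
        return "F+S"
    if c.n_fuc >= 1:
        return "only_F"
    if c.n_neuac >= 1:
        return "only_S"
    if is_high_mannose(c):
        return "HM"
    return "Other"


def classify_antenna_class(c: GlycanComposition) -> str:
    """Assign one of the antenna classes A-E.

    A: high mannose; B: low antenna (non-HM, N <= 3); C: mid antenna,
    low sialylated (4 <= N <= 5, S <= 1); D: mid antenna, high
    sialylated (4 <= N <= 5, S >= 2); E: high antenna (N >= 6).
    """
    if is_high_mannose(c):
        return "A"
    if c.n_hexnac <= 3:
        return "B"
    if 4 <= c.n_hexnac <= 5:
        return "D" if c.n_neuac >= 2 else "C"
    return "E"


@dataclass(frozen=True)
class GlycanDatabaseEntry:
    """One glycan database row: a composition and its neutral mass."""

    composition: GlycanComposition
    neutral_mass: float

    @classmethod
    def from_composition(cls, c: GlycanComposition) -> "GlycanDatabaseEntry":
        return cls(composition=c, neutral_mass=composition_mass(c))


@dataclass(frozen=True)
class GlycoformKey:
    """Unique glycoform identity: protein, gene, site, composition.

    Serialized as ``protein_gene_site_composition``.  Protein accessions
    with internal underscores are tolerated only when the gene symbol is
    underscore-free, because parsing splits from the right.
    """

    protein_id: str
    gene: str
    site: int
    composition: GlycanComposition

    def __post_init__(self) -> None:
        if self.site < 1:
            raise ValueError(f"site must be >= 1, got {self.site}")

    def __str__(self) -> str:
        return f"{self.protein_id}_{self.gene}_{self.site}_{self.composition}"


def parse_glycoform_key(text: str) -> GlycoformKey:
    """Parse a ``protein_gene_site_composition`` glycoform key."""
    parts = text.strip().rsplit("_", 2)
    if len(parts) != 3:
        raise GlycanParseError(f"malformed glycoform key {text!r}")
    head, site_str, comp_str = parts
    if "_" not in head:
        raise GlycanParseError(f"malformed glycoform key {text!r}: missing gene field")
    protein_id, gene = head.rsplit("_", 1)
    try:
        site = int(site_str)
    except ValueError:
        raise GlycanParseError(f"non-integer site {site_str!r} in key {text!r}") from None
    return GlycoformKey(protein_id, gene, site, parse_composition(comp_str))


def load_glycan_db(path: str | Path) -> list[GlycanDatabaseEntry]:
    """Load a glycan database from a TSV file.

    Column 1 is the composition string; an optional column 2 gives a
    user-supplied neutral mass overriding the computed one.  Rows are
    deduplicated by composition (first occurrence wins).
    """
    entries: dict[GlycanComposition, GlycanDatabaseEntry] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                comp = parse_composition(fields[0])
            except GlycanParseError as exc:
                raise GlycanParseError(f"{path}:{lineno}: {exc}") from None
            if len(fields) > 1 and fields[1].strip():
                try:
                    neutral_mass = float(fields[1])
                except ValueError:
                    raise GlycanParseError(
                        f"{path}:{lineno}: non-numeric mass {fields[1]!r}"
                    ) from None
            else:
                neutral_mass = composition_mass(comp)
            entries.setdefault(comp, GlycanDatabaseEntry(comp, neutral_mass))
    if not entries:
        logger.warning("glycan database %s is empty", path)
    return list(entries.values())


def write_glycan_db(entries: Iterable[GlycanDatabaseEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f"{e.composition}\t{e.neutral_mass:.6f}\n")
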