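"""Physical constants and ion masses used throughout the package.

Monoisotopic residue masses are computed from atomic compositions via
:mod:`pyteomics.mass` so there is a single source of truth.  All masses
are in daltons; all m/z values in thomson.
"""

from pyteomics import mass as _pmass

PROTON: float = 1.00727646688
WATER: float = _pmass.calculate_mass(formula="H2O")

#: Monoisotopic residue masses of the five monosaccharide classes.
MONOSACCHARIDE_FORMULAS = {
    "HexNAc": "C8H13N1O5",
    "Hex": "C6H10O5",
    "dHex": "C6H10O4",  # fucose
    "NeuAc": "C11H17N1O8",
    "NeuGc": "C11H17N1O9",
}
MONOSACCHARIDE_MASSES = {
    name: _pmass.calculate_mass(formula=f) for name, f in MONOSACCHARIDE_FORMULAS.items()
}

# Diagnostic oxonium ions (singly protonated glycan fragments).
OXONIUM_HEXNAC: float = MONOSACCHARIDE_MASSES["HexNAc"] + PROTON            # 204.0866
OXONIUM_HEX: float = MONOSACCHARIDE_MASSES["Hex"] + PROTON                  # 163.0601
OXONIUM_HEXNAC_HEX: float = OXONIUM_HEXNAC + MONOSACCHARIDE_MASSES["Hex"]   # 366.1395
OXONIUM_NEUAC: float = MONOSACCHARIDE_MASSES["NeuAc"] + PROTON              # 292.1027
OXONIUM_NEUAC_H2O: float = OXONIUM_NEUAC - WATER                            # 274.0921
OXONIUM_HEXNAC_HEX_FUC: float = OXONIUM_HEXNAC_HEX + MONOSACCHARIDE_MASSES["dHex"]  # 512.1974
# Hex-series ions indicative of high-mannose glycans.
OXONIUM_HEX2: float = 2 * MONOSACCHARIDE_MASSES["Hex"] + PROTON             # 325.1129

#: Fixed/variable modification masses.
MOD_CARBAMIDOMETHYL: float = _pmass.calculate_mass(formula="C2H3N1O1")  # +57.021464 on C
MOD_TMT: float = 229.162932  # TMT 10/11-plex label, N terminus and K
MOD_OXIDATION: float = _pmass.calculate_mass(formula="O1")  # +15.994915 on M

#: TMT-11 reporter ion m/z values (channel name -> m/z).
TMT11_REPORTERS = {
    "126": 126.127726,
    "127N": 127.124761,
    "127C": 127.131081,
    "128N": 128.128116,
    "128C": 128.134436,
    "129N": 129.131471,
    "129C": 129.137790,
    "130N": 130.134825,
    "130C": 130.141145,
    "131N": 131.138180,
    "131C": 131.144499,
}

#: Averagine model: average atomic composition per dalton of peptide mass.
AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
AVERAGINE_MASS = 111.1254

#: Spacing between isotope peaks (mass of a neutron exchange C12->C13, effectively).
ISOTOPE_SPACING: float = 1.00335
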