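"""Parse glycan compositions and apply the two classification schemes.

Compositions are written NxHyFzSwGv (HexNAc, Hex, fucose, NeuAc,
NeuGc).  The five glycan types describe terminal decoration (high
mannose, fucosylated only, sialylated only, both, other); the five
antenna classes A-E use the HexNAc count as a branching proxy and the
NeuAc count for terminal capping.
"""

from igpkit.glycans import (
    classify_antenna_class,
    classify_glycan_type,
    composition_mass,
    parse_composition,
    parse_glycoform_key,
)

for text in ["N2H8F0S0G0", "N3H6F1S1G0", "N4H5F0S2G0", "N6H7F1S2G0", "N3H4F0S0G0"]:
    c = parse_composition(text)
    print(
        f"{text}: mass {composition_mass(c):9.4f} Da, "
        f"type {classify_glycan_type(c):6s}, antenna class {classify_antenna_class(c)}"
    )

key = parse_glycoform_key("ENSP00000243077_LRP1_1575_N3H6F1S1G0")
print(f"\nglycoform key -> protein {key.protein_id}, gene {key.gene}, "
      f"site N{key.site}, glycan {key.composition}")
# N2H8 is a classic high-mannose glycan (type HM, class A); N3H6F1S1
# carries both fucose and NeuAc (type F+S) but has too few HexNAc for a
# mid-antenna class, so it falls in class B.
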