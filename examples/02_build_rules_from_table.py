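"""Build GPR/S-GPR rules from an enzyme-composition table.

The table lists, per EC code and compartment, the catalytic units
(isoenzymes or complexes) and the genes composing them with copy numbers.
Units of one EC join by OR (any isoenzyme suffices), genes within a unit
by AND (all subunits required), and rows from the wrong compartment are
filtered out against the reaction's inferred location.
"""

from sgprflux import CompositionRow, ReactionAnnotation, build_gpr_for_reaction, serialize_gpr

table = [
    CompositionRow("1.1.1.1", "c", "complex1", "a", 1),
    CompositionRow("1.1.1.1", "c", "complex1", "b", 2),
    CompositionRow("1.1.1.1", "c", "iso2", "z", 1),
    CompositionRow("1.1.1.1", "m", "mito_iso", "q", 1),  # wrong compartment
]
annotation = ReactionAnnotation("R1", ec_codes=["1.1.1.1"], compartment="c")
tree = build_gpr_for_reaction(annotation, table)
print("cytosolic reaction R1:")
print("  S-GPR:", serialize_gpr(tree, "SGPR"))
print("  GPR:  ", serialize_gpr(tree, "GPR"))
print("The mitochondrial isoenzyme (gene q) was excluded by the compartment filter;")
print("the complex needs two copies of b, the single-gene isoenzyme z is an OR branch.")
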