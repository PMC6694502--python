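"""Parse and evaluate stoichiometric gene-to-reaction rules.

A reaction catalyzed by a three-subunit complex — one subunit from gene a,
two from gene b — has classical GPR "a and b" but S-GPR "a and 2*b": gene
b must supply two transcript copies per functional complex, so its
expression is halved before the AND (minimum) is taken.
"""

from sgprflux import ExpressionProfile, GprConfig, evaluate_gpr, parse_gpr, serialize_gpr

tree = parse_gpr("a and 2*b")
print("S-GPR :", serialize_gpr(tree, "SGPR"))
print("GPR   :", serialize_gpr(tree, "GPR"))

profile = ExpressionProfile(values={"a": 4.0, "b": 10.0})
gpr_score = evaluate_gpr(tree, profile, GprConfig(gpr_mode="GPR"))
sgpr_score = evaluate_gpr(tree, profile, GprConfig(gpr_mode="SGPR"))
print(f"expression a=4, b=10 -> GPR score min(4, 10) = {gpr_score}")
print(f"                        S-GPR score min(4, 10/2) = {sgpr_score}")
# Identical here because a is limiting either way; raise a and the copy
# number of b starts to matter:
profile2 = ExpressionProfile(values={"a": 12.0, "b": 10.0})
print(
    "expression a=12, b=10 -> GPR",
    evaluate_gpr(tree, profile2, GprConfig(gpr_mode="GPR")),
    "vs S-GPR",
    evaluate_gpr(tree, profile2, GprConfig(gpr_mode="SGPR")),
    "(b's two-copy requirement now limits the complex)",
)
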