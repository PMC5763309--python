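"""The small hand-checkable instance used throughout the docs.

Walks the three primitives on fixed inputs: semantic contributions on a
three-term is-a chain, candidate expansion on a triangle with a pendant
node, and the affinity score of two size-2 complexes sharing one protein.
"""

from cpredictor3 import (
    CandidateComplex,
    affinity_score,
    expand_candidate,
    semantic_contributions,
    semantic_value,
    small_worked_fixture,
    term_similarity,
)

fx = small_worked_fixture()

print("== Wang semantic contributions on the chain C is_a B is_a A ==")
smap = semantic_contributions(fx.dag, "C")
for term in ("C", "B", "A"):
    print(f"  S_C({term}) = {smap[term]:.2f}")
print(f"  SV(C) = {semantic_value(fx.dag, 'C'):.2f}")
print(f"  S_GO(B, C) = {term_similarity(fx.dag, 'B', 'C'):.4f}")
print("  (each ancestor contributes the best edge-weight product of a path to C;")
print("   B and C share ancestry {A, B}, giving similarity below 1)")

print("\n== Expansion of the triangle {a, b, c}; x interacts with a and b ==")
seed = CandidateComplex(fx.seed_complex)
for alpha in (1.0, 0.6):
    grown = expand_candidate(seed, fx.ppi, alpha)
    verdict = "admitted" if "x" in grown.members else "rejected"
    print(f"  alpha={alpha}: x has 2 edges vs threshold {alpha * 3:.1f} -> {verdict}")

print("\n== Affinity score of P={a,b} and R={b,c} ==")
score = affinity_score(*fx.affinity_pair)
print(f"  AS = |P n R|^2 / (|P|*|R|) = {score}")
print(f"  {score} >= 0.2, so a size-2 prediction would 'match' almost by accident —")
print("  which is why predicted complexes of size 2 are discarded by default.")
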