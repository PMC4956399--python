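"""Design-library accounting: landscape size, design budget, top-K selection.

Builds a small synthetic scored candidate pool from three design strategies
and selects the best-scoring unique variants per strategy.
"""

from collections import Counter

from designscreen import library, synthetic

# An 18-residue window over 20 amino acids spans ~2.6e23 sequences — far
# beyond any screening library, which is why a designed library is needed.
print(f"landscape size (18 positions): {library.landscape_size(18, 20):.2e}")
print(f"landscape size (8 positions):  {library.landscape_size(8, 20):.2e}")
print(f"design budget (2500 backbones x 25 designs): {library.design_budget(2500, 25)}")

gt = synthetic.make_ground_truth(seed=1)
candidates = synthetic.simulate_design_candidates(
    gt, ["MD", "CONCOORD", "Backrub"], n_per_strategy=5000, seed=2
)
selected = library.select_top_candidates(candidates, k_per_strategy=500)
print(f"\ncandidates: {len(candidates)}, selected: {len(selected)} "
      f"({Counter(r.strategy for r in selected)})")
print(f"globally unique sequences: {len({r.window_seq for r in selected})}")
best = selected[0]
print(f"example selected variant: {best.id} {best.window_seq} score={best.score:.2f}")
print("(lower score = tighter predicted binding; duplicates across strategies "
      "are assigned to the strategy where they score best)")
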