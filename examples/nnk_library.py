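"""Biased-NNK naive library: closed-form amino-acid distribution vs simulation.

NNK degenerate codons (N=A/C/G/T, K=G/T) encode all 20 amino acids in 32
codons with a single stop (TAG); biasing each base 70% toward the wild-type
nucleotide emulates large "biased naive" phage libraries.
"""

from designscreen import library, synthetic

wt_nt = library.reverse_translate(synthetic.DEFAULT_WT_WINDOW)
spec = library.NaiveLibrarySpec(
    wt_nt=wt_nt, wt_bias=0.70, n_sequences=100_000, n_replicates=2
)

freq, stop = library.expected_aa_frequency(spec, position=0)
wt_aa = synthetic.DEFAULT_WT_WINDOW[0]
print(f"position 1 (wild type {wt_aa}): exact P({wt_aa}) = {freq[wt_aa]:.3f}, "
      f"stop mass = {stop:.4f}")
print("top alternatives:", ", ".join(
    f"{aa}={p:.3f}" for aa, p in freq.drop(wt_aa).nlargest(3).items()))

reps = library.simulate_nnk_library(spec, seed=5)
obs = sum(s[0] == wt_aa for s in reps[0]) / len(reps[0])
print(f"simulated P({wt_aa}) at position 1 over {spec.n_sequences} draws: {obs:.3f}")
print("(stop-containing windows are discarded and redrawn, so each replicate "
      "holds exactly n_sequences stop-free windows)")

unbiased = library.NaiveLibrarySpec(wt_nt=wt_nt, wt_bias=0.0, n_sequences=1)
_, stop0 = library.expected_aa_frequency(unbiased, 0)
print(f"unbiased NNK stop probability per codon: {stop0:.4f} (exactly 1/32)")
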