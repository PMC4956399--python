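# designscreen

Analytics for **computationally designed protein-variant screens**: the
workflow in which a designed library (thousands of variants proposed by
structure-based design over an ensemble of backbones) is screened by
selection — phage display or yeast two-hybrid — and read out by deep
sequencing, with read counts serving as a surrogate for binding affinity.

The package covers the computational side of that workflow end to end,
driven by a seeded synthetic-data generator so every stage runs without
external downloads:

- **library accounting** — exact landscape sizes (`20^18 ≈ 2.6e23` for an
  18-residue window), design budgets, top-K selection of unique variants
  per design strategy with a deterministic cross-strategy deduplication
  rule, and reverse translation to oligonucleotides;
- **naive-library simulation** — biased NNK degenerate-codon libraries
  (N = A/C/G/T, K = G/T; 32 codons, one stop) with a configurable
  wild-type nucleotide bias, plus the exact closed-form per-position
  amino-acid distribution the simulator must converge to;
- **read QC** — Phred filtering (minimum Q30 with an optional allowance of
  a few positions down to Q20), anchor-based extraction and translation of
  the designed window, and thresholded tallying into count tables
  (count ≥ 2 for phage pools, ≥ 5 for Y2H);
- **sequence statistics** — position frequency profiles, information
  content in bits (IC = log₂20 − H), Jensen-Shannon divergence between
  profiles (base 2, ≤ 1 bit), divergence from the wild-type window, and
  PCA of one-hot encoded sequences;
- **read-count surrogate** — an ensemble of random-forest regressors
  predicting log₁₀ read count from sequence; each forest pairs the
  selected variants with a fresh draw of random negative sequences at a
  pseudo-count of 10⁻¹⁰ (target −10), hyperparameters are chosen by
  grid search under class-balanced 5-fold CV scored by Spearman
  correlation, predictions are ensemble medians, and a threshold
  calibrated on a known tight binder turns predictions into hit calls and
  hit-rate **enrichment factors** of designed over naive libraries;
- **affinity extrapolation** — the log-count/IC₅₀ regression used to put
  an IC₅₀ bound on sequenced variants, and four-parameter-logistic
  dose-response fitting
  (`y = bottom + (top − bottom)/(1 + (c/IC₅₀)^h)`);
- **structural rescoring** — PDB I/O, Kabsch superposition and RMSD,
  backbone-ensemble PCA against a reference set, interface-contact
  detection within a 5 Å shell (optionally restricted to side chains
  oriented toward the partner), and a 12-6 Lennard-Jones interface score
  `4ε[(σ/r)¹² − (σ/r)⁶]` with Lorentz–Berthelot combination, split into
  attractive/repulsive parts and evaluated by Spearman rank correlation
  against read counts.

## Worked example

The library API is the primary interface; `examples/` holds one short
script per capability. Running the full pipeline:

```bash
python examples/full_pipeline.py      # or: designscreen run -c config.yaml
```

prints (abridged):

```
[library]
  n_candidates: 3000
  n_selected: 450
  n_unique: 450
[screen]
  n_reads: 34991
  n_variants_counted: 148
[qc]
  reads_pass_quality: 29949
  variants_retained: 105
[stats]
  divergence_from_wt_pct: {'Backrub': 52.037, 'CONCOORD': 56.704, 'MD': 54.815}
  mean_jsd_bits: {'Backrub|CONCOORD': 0.1326, 'Backrub|MD': 0.1267, 'CONCOORD|MD': 0.1343}
[struct]
  median_rmsd: 0.4411
```

Reading: three design strategies each contributed 150 selected variants
(all globally unique); four selection rounds at 30k depth left 148
variants with reads, of which 105 survived quality filtering and the
count-≥2 threshold; the designed sequences differ from the wild-type
window at 52–57% of positions while the strategies' residue usage differs
by ~0.13 bits of Jensen-Shannon divergence; the structural ensemble sits
at 0.44 Å median Cα RMSD from its reference. `examples/surrogate_enrichment.py`
continues into surrogate training, threshold calibration, enrichment over
naive NNK replicates and the IC₅₀ fits.

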