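# Methods

## The screening workflow being modelled

A designed protein-variant screen couples three measurements: a *designed
library* (variants proposed by structure-based design over backbone
ensembles from several strategies), *selection read counts* (deep
sequencing of the pool surviving several rounds of phage display or a
yeast two-hybrid selection), and *per-variant validation* (dose–response
IC₅₀). The analytical chain this package implements takes scored design
candidates to a selected library, selection FASTQ to a quality-controlled
count table, count tables to a sequence-to-count surrogate model with hit
calls and enrichment factors, and structural ensembles to an interface
rescoring. A synthetic-data generator supplies every input with seeded
reproducibility, so the whole chain is testable closed-loop.

## The synthetic ground truth

The generator's central object is an additive affinity landscape over an
18-residue window (defaulting to human ubiquitin residues 54–71,
`RTLSDYNIQKESTLHLVL`): `affinity(s) = Σᵢ E[i, sᵢ]`, lower = tighter.
Additivity is a deliberate simplification — it makes closed-form oracles
exact (per-position argmin, exact expected counts) at the cost of
ignoring epistasis; conclusions from passing tests therefore concern the
pipeline's bookkeeping and statistics, not the ruggedness of real
landscapes.

Three structural choices make the landscape behave like a real design
target:

- **Mixed conservation.** The wild-type residue at each position receives
  an energy bonus drawn uniformly from [0, 2·`wt_favor`] (default mean
  3 kT-like units against a unit-variance random background). Strongly
  conserved positions coexist with tolerant ones, so Boltzmann-sampled
  designs diverge from wild type at roughly half the positions while the
  best designs still beat wild type — the regime reported for real
  designed binder sets.
- **Hotspots.** `n_hotspots` positions (default 3) carry a favored
  non-wild-type residue whose energy is set exactly `effect_size`
  (default 2) below the wild-type residue's, emulating critical interface
  mutations. The variant "wild type + all hotspots"
  (`GroundTruth.reference_binder()`) stands in for a previously
  characterized tight binder and anchors threshold calibration.
- **Strategy structure.** Each design strategy samples per-position
  residues from `exp(−(E + Δ_strategy)/T)` where `Δ_strategy` is a
  strategy-specific Gaussian offset (scale `strategy_spread`, default
  0.75) and `T` is the sampling temperature (default 1.0). Strategies
  thus genuinely prefer different sequence regions (positive
  Jensen-Shannon divergence between their profiles) and differ in
  quality, as the three strategies in real screens do. `T → 0` collapses
  onto the strategy optimum; with `strategy_spread = 0` that is the
  global landscape optimum.

**Counts.** After `r` selection rounds at sequencing depth `D`, a
variant's expected count is `D · wᵥ/Σw` with
`log₁₀ wᵥ = −slope · r · affinity(v)` (slope 0.15/round by default), so
expected log₁₀ count is affine and *decreasing* in affinity and the slope
scales linearly with rounds. Realized counts are negative-binomial via a
gamma–Poisson mixture (`var = μ + φμ²`, overdispersion φ = 0.3;
φ = 0 gives Poisson). The affinity→count noise model is not reported for
real screens; the negative binomial is the standard overdispersed choice
for amplicon counts and is flagged as a stand-in. The slope default keeps
a selected pool of a few hundred variants represented at depth 10⁵,
matching the ~2×10² variant pools such screens train on.

**Reads** are single-end (pairing would add nothing to the computation
being exercised): left anchor + oligo + right anchor, substitution errors
i.i.d. per base at `error_rate`, and Phred strings that mark exactly the
error positions with the low quality score (default Q12 vs Q38). This
makes quality filtering maximally informative in the closed loop; real
quality strings are noisier about where errors lie.

**Structures** are toy two-chain complexes (variant strand facing a
partner strand, five atoms per residue). Ensemble members add smooth
per-residue Gaussian jitter whose 3-D RMS magnitude is `displacement_sd`
(a 3-point L2-normalized smoothing kernel keeps the marginal scale while
making neighbours move coherently), then a random rigid transform that
superposition must remove. **Dose–response curves** are 4PL with
Gaussian noise; at `c = IC₅₀` the noise-free response is exactly the
midpoint.

## Analysis conventions and numerical choices

- **Phred threshold** "minimum above 30" is implemented inclusively
  (quality ≥ 30 passes), the conventional reading; a `strict` flag gives
  the literal > 30. The low-quality exemption is exposed as
  `(n_exempt, exempt_min)` — (0, –) for phage, (3, 20) for Y2H.
- **Count thresholds** are inclusive (≥ 2 phage, ≥ 5 Y2H).
- **NNK bias branch is unconditional**: with probability `wt_bias` the
  wild-type base is kept even where it lies outside the scheme's allowed
  set at that slot (e.g. wild-type A at a K slot). The closed-form
  `expected_aa_frequency` marginalizes the same mixture, so simulator and
  formula agree exactly. Stop-containing windows are redrawn under the
  default `discard` policy (set sizes stay exact); `keep-flagged` keeps
  `*` for frequency audits — convergence checks against the closed form
  use `keep-flagged`, since discarding renormalizes away the stop mass.
- **Logs are base 10** throughout the surrogate (negative pseudo-count
  10⁻¹⁰ → target −10). Information content and JSD are base 2 (bits);
  the small-sample logo correction 19/(2·ln2·n) is off by default.
- **Forest hyperparameters** map node size → `min_samples_leaf` and
  variables-per-split → `max_features` on the one-hot expansion
  (window_length × 20 binary features). Default grid
  {3, 5, 9} × {3, 7, 12}; CV folds interleave a shuffled permutation so
  positives and negatives are balanced per fold; grid ties resolve to the
  first point in row-major order. Forests default to 100 trees each — at
  a few hundred training samples the ensemble median is stable well below
  the 500-tree default of R's randomForest, and a 100-forest ensemble
  trains in seconds.
- **Enrichment** is the hit-rate ratio (designed fraction ÷ mean naive
  fraction), independent of library sizes. Zero naive hits across all
  replicates reports the factor as infinite with an explicit flag: at
  desk scale (10⁴-sequence naive replicates) this is the *expected*
  outcome of the realistic regime, where naive hit rates are ~10⁻⁵.
- **Hit-precision evaluation** (acceptance suite) therefore probes a pool
  with planted structure — the designed library plus a 10⁴-sequence
  naive NNK probe — labelling "tight" as true affinity at least as good
  as the median training positive; hit-call precision is compared to the
  pool base rate.
- **IC₅₀/count line** defaults to regressing log₁₀ IC₅₀ on log₁₀ count
  (dose–response plots are log-scaled); a `linear` mode fits raw IC₅₀.
  Pearson r is computed on the fitted scale.
- **4PL fitting** uses bounded Levenberg–Marquardt (trust-region) least
  squares with IC₅₀ constrained positive, initialized at the observed
  response extremes and the concentration nearest the midpoint; a flat
  response raises before optimization (unidentifiable IC₅₀).
- **Kabsch RMSD** pairs atoms by (chain, residue, atom name), solves the
  rotation with `scipy`'s `align_vectors`, and recomputes the residual
  explicitly (the library's returned residual cancels badly near zero).
- **The LJ score is a plain 12-6 potential** with per-element σ/ε
  (generic force-field magnitudes, versioned table v1), Lorentz–Berthelot
  combination, hard cutoff (default 8 Å) and optional truncate-shift.
  Softened/switched force-field variants are intentionally not
  reproduced: the scientific content of the rescoring step is *which*
  atom pairs are scored (interface side chains within a short shell), and
  a plain potential keeps the score oracle-testable. "Side chain oriented
  toward the interface" is operationalized as the side-chain centroid
  lying nearer the partner chain than the backbone centroid.
- **Selection tie-breaks**: cross-strategy duplicate sequences are
  assigned to the strategy where they score best (further ties by
  strategy label, then id); score ties at the per-strategy cutoff break
  by lexicographic sequence. Both rules exist purely for determinism.

## Problem sizes

Defaults in tests and the demo pipeline are desk-scale by design:
candidate pools of 2 000–62 500 per strategy, selection depths 10⁴–10⁵,
naive NNK sets of 10⁴ (×3 replicates) against the 10⁶ (×10) of a
full-scale comparison, 100-forest ensembles of 100 trees, and structural
ensembles of 25–100 models. All sizes are configuration parameters; the
full-scale candidate generation (3 × 62 500) runs in seconds and is
exercised by the acceptance script.

## Known limitations

- The additive landscape cannot represent epistasis; surrogate
  performance on it is an upper bound relative to rugged real landscapes.
- Strategy differences are injected as random landscape offsets, not
  derived from structural ensembles, so agreement between sequence-space
  and structure-space strategy separation is not modelled.
- Synthetic reads are single-end, anchor-perfect apart from substitution
  errors; no indels, chimeras, adapter artefacts or barcode issues.
- Toy complexes are strand-on-strand; LJ scores are meaningful as
  rankings within an ensemble, not as physical energies.
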