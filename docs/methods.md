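# Methods

This note states, in the package's own terms, exactly what each analysis
stage computes and which choices were made where conventions diverge.

## Supermatrix construction and statistics

Per-locus alignments are concatenated over the union of their taxa in
first-appearance order; a taxon missing from a locus contributes a block of
`?` (missing) symbols, and a partition map records each locus as a 1-based
inclusive column range.  Occupancy of a locus is the number of taxa with at
least `min_residues` unambiguous characters inside its range
(`min_residues=1` by default — the most permissive defensible criterion,
exposed as a parameter because published occupancy figures rarely state
theirs).  The summary reports locus-length and occupancy ranges and means,
per-taxon residue counts, and per-taxon completeness (fraction of
supermatrix columns holding an unambiguous character).

## Substitution models and likelihoods

Amino-acid models are reversible CTMCs assembled from an exchangeability
matrix and equilibrium frequencies (LG, WAG, MtZoa built in; Poisson and
arbitrary matrices supported).  The rate matrix is normalized to one
expected substitution per unit branch length, and `P(t)` is computed
through the symmetric eigendecomposition of `D^{1/2} Q D^{-1/2}`.  `+F`
replaces the model's frequencies with empirical ones (pseudo-frequency of
`1/(2 * total residues)` guards against absent states).  `+G` uses the
mean-per-category discretization of a Gamma(shape, rate = shape) density
into equal-probability categories.

Tree log-likelihoods use Felsenstein pruning with per-node scaling and
site-pattern compression; ambiguous characters and gaps contribute a
partial likelihood of 1 in every state.  Branch lengths are fitted by
coordinate ascent (bounded Brent per branch on `[1e-8, 20]`, monotone in
the total lnL); the gamma shape can be profiled the same way.

## Topology tests

Given the per-site lnL matrix of the candidate trees:

* **delta-lnL.**  Two conventions are exposed rather than silently picking
  one: `"table"` = `lnL(null) − lnL(alt)` (positive when the null fits
  better; matches published comparison tables built this way) and
  `"equation"` = `2(lnL(alt) − lnL(null))` (the textbook deviance scale).
  They disagree in sign and scale; callers must choose explicitly.
* **RELL bootstrap.**  Replicate totals are multinomial resamples of site
  counts applied identically to every tree (paired resampling), computed
  as a counts-matrix product; trees are never re-optimized.
* **AU test.**  For scales r in 0.5…1.4 (step 0.1), `ceil(r·n)` sites are
  resampled per replicate and each tree's winning proportion (BP) is
  recorded, with ties broken uniformly at random.  BPs are clipped to
  `[1/(2B), 1 − 1/(2B)]`, mapped through `z = Φ⁻¹(1 − BP)`, and
  `z(r) = d·√r + c/√r` is fitted by weighted least squares with binomial
  variance weights; `p_AU = 1 − Φ(d − c)`.  A tree winning (losing) every
  replicate at every scale carries no curvature information and is
  reported saturated at `1 − 1/(2B)` (resp. `1/(2B)`); with a single scale
  the naive BP is returned.
* **BIC posteriors.**  `posterior_i ∝ exp(lnL_i − penalty_i/2)`, evaluated
  with a max shift and log-sum-exp.  Equal penalties (same model, same
  parameter dimension across fixed topologies) cancel, leaving a softmax
  over total log-likelihoods.

## Marginal likelihoods and Bayes factors

The log marginal likelihood of a fixed-topology MCMC run is the harmonic
mean of the sampled likelihoods, computed in log space as
`−(logsumexp(−lnL) − ln n)`; this estimator is upwardly biased and
high-variance, which the test suite verifies directionally.  The moving
variant re-estimates over a sliding window of `max(1, ceil(f·i))` samples
(default `f = 0.33`) to expose trend; chains are pooled before the final
estimate.

The default Bayes-factor transformation is the *log-of-difference* form
`BF₁₀ = sign(Δ) · 2·ln|Δ|` with `Δ = marginal(T1) − marginal(T0)` on the
log-marginal scale — a non-standard formula reproduced deliberately
because it is what the source analysis prints (it maps `Δ = e²` to 4.0 and
`Δ = e^5.24` to 10.48).  The textbook `2Δ` is available as
`formula="standard"`.  Evidence bands on |BF₁₀|: `< 2` none, `2–6` some,
`6–10` strong, `≥ 10` very strong.

## Bait design

Reference sequences are cleaned (maximal N-runs of ≤ 10 replaced by T-runs;
fragments right-padded with T to 120 bp), tiled into 120-mers every 50 bp
(~2.4× density), and rejected immediately if they retain an N or exceed 25%
soft-masked content.  Alignment hits count only when strictly longer than
45 bp and strictly above 75% identity.  A candidate is retained when it has
at most 10 qualifying hits with melting temperature in 62.5–65 °C
(inclusive bounds), at most 2 above 65 °C, and passes a pluggable
flanking-region predicate (pass-through by default; the published wording
of that rule is ambiguous, so the interpretation is injectable rather than
hard-coded).  Tm defaults to the salt-adjusted GC/length approximation
`81.5 + 16.6·log₁₀[Na⁺] + 0.41·%GC − 600/len − (100 − %identity)`.

## Synthetic data

Every stage has a generator that is a pure function of its arguments and a
seed: forward CTMC simulation along a tree (root states from equilibrium,
per-site gamma categories), occupancy matrices with study-shaped defaults
(134 loci, 44 taxa, lengths 56–363, occupancy 5–36), stationary AR(1)
log-likelihood traces (marginal `N(mean, sd²)` at every lag), truncated-
normal site-lnL matrices with controlled between-tree offsets, and a
hand-enumerable bait fixture placing candidates on both sides of every
threshold.  A run seed fans out to per-purpose child seeds via a
`SeedSequence` keyed on (seed, CRC-32 of a label).
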