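# Methods

## Model and procedure

### Mismatch features and the LR test

A motif candidate is a fixed core *w*-mer *c*. Its mismatch statistic for a
sequence *S* is the minimum over all width-*w* windows *x* of
min(H(c,x), H(rc(c),x)) — strand-aware because a binding site is equally
functional on either strand. Positions holding the ambiguity code N count
as mismatches, so an undetermined stretch can never manufacture a match.

Discovery enumerates every N-free window of every foreground sequence as a
candidate (optionally at a stride > 1 for speed). For each candidate, the
cluster label is regressed logistically on the mismatch feature with the
candidate's source sequence removed from the fit — the window was selected
*from* that sequence, so keeping it would bias the test. The likelihood
ratio against the intercept-only null is referred to χ²₁ (Wilks), and the
full candidate family is corrected by Benjamini–Hochberg. Because every
enumerated window is tested, the number of hypotheses is well defined and
the q-values are interpretable; under a global null the BH procedure also
bounds the family-wise error, which is what the calibration experiment
measures.

The χ² test is two-sided, so a core conspicuously *absent* from the
foreground can reach a small p-value with a positive mismatch coefficient.
Such an anti-motif is not a binding-site model, and a PWM seeded from it
ranks background above foreground. The retained motif is therefore the most
significant candidate with coefficient ≤ 0 (enriched in the foreground); if
no candidate is enriched the global minimum is reported as-is. q-values are
still computed over the full family, which keeps the reported FDR
conservative.

### Seed PWM

With c\* the winning core, the threshold t is the median over background
sequences of D_{c\*}(S); the seed set is every foreground window at
distance strictly below t — "matches the core better than the typical
background sequence manages anywhere". The median over an even number of
sequences is the mean of the two central order statistics; since distances
are integers and the comparison is strict, the half-integer threshold is
unambiguous. If the seed set is empty (t = 0), the single best window of
each foreground member is used instead, so a PWM is always defined. Each
selected window enters the PWM in whichever orientation (forward or reverse
complement) is closer to c\*, so instances found on opposite strands align;
without this the PWM would average a motif with its reverse complement.
The PWM uses a pseudocount of 1.

### ALR: conditioning on bulk composition

Real clusters differ in low-order composition (GC content, dimer
frequencies), and a long "motif" can be significant merely because of that.
ALR replaces the intercept-only null with intercept + the m
reverse-complement-collapsed spectrum features (2 monomer + 10 dimer
classes) that are individually most predictive, ranked by single-feature
logistic likelihood with lexicographic tie-breaks. Feature selection reuses
the full training data and is not repeated inside the leave-one-out loop,
matching the procedure it implements. The final ALR classifier is a
logistic model on the m features plus the seed-PWM score; its predicted
probability is the score that enters the benchmark. Defaults w = 12 and
m = 5 are configurable; all experiments here state their widths explicitly.

### Logistic fitting

All fits use one Newton–Raphson solver (log-likelihood tolerance 1e-8, max
100 iterations, step-halving safeguard), vectorized across candidates with
per-candidate leave-one-out weights, so a discovery run performs thousands
of exact MLE fits in a few matrix operations. Under perfect separation the
likelihood supremum is 0 and coefficients diverge; they are clamped at
|β| ≤ 30 and the fit is flagged, which keeps Λ finite and maximal. A tiny
ridge (1e-9) regularizes near-singular Hessians. The scalar fit exposed as
`fit_logistic` is the same algorithm and is cross-checked against
statsmodels in the test suite.

### Benchmark protocol

Clusters below 10 members are excluded; clusters above 200 are subsampled.
Each cluster is split into equal halves (train takes the ceiling on odd n);
200 background sequences (100 train / 100 validation) are drawn without
replacement from the union of the other clusters, excluding any id present
in the foreground. LR and true-PWM methods are scored by the PWM window
score F(S) (max likelihood over all windows of S and rc(S), N scoring a
neutral 0.25 per position, computed in log space); ALR by its final-model
probability. AUROC uses the Mann–Whitney formulation with midrank ties, so
any strictly increasing transform of a score gives the identical value.
One split per cluster is drawn (repetition is not the default), and the
same root seed drives every draw, so different methods run under the same
configuration are compared on identical splits.

### Planted-motif simulation and the Bayes bound

Background sequences are i.i.d. with P(C)=P(G)=gc/2 (gc = 0.4 throughout,
the yeast-like setting). Each cluster gets one PWM — drawn without
replacement while the list lasts, then with replacement — and every member
receives one sampled instance overwriting a uniformly chosen offset on the
forward strand, preserving sequence length. Because both background and
instance positions are generated independently, the naive-Bayes
factorization of the likelihood is exact, and the posterior classifier
(equal cluster priors, plant position marginalized by log-sum-exp over all
offsets) is Bayes optimal. The sum over positions is not divided by
L − w + 1; with near-equal motif widths the missing constant is negligible
and cancels exactly when widths are equal. A both-strands variant of the
posterior exists behind a flag for sensitivity analysis, but the default
matches the forward-only planting. Ties in the argmax are counted as
correct with probability 1/|tie set| (expected accuracy), keeping results
deterministic.

The synthetic PFMs (`random_peaked_pfm`) emulate curated transcription
factor matrices: a random consensus holding 90% of 100 counts per column,
i.e. ≈0.87 probability on the consensus base after the unit pseudocount
(~1.1 bits per column). A count total of order 100 mirrors the number of
aligned sites behind curated matrices; with much smaller totals the
pseudocount flattens the probability view and the motif is no longer
sharply peaked.

### Background-model diagnostics

*A/T overdispersion.* An r-th order Markov chain (pseudocount-smoothed
conditionals, empirical smoothed initial r-mer distribution) is fitted to a
sequence pool; for each observed sequence length, B = 200 replicates are
sampled and the observed A/T fraction is converted to a Z-score against the
replicate mean and sd (shared across sequences of equal length — the
matching is per length, since A/T-fraction variance scales with 1/L).
Sequences shorter than 100 nt are dropped; entries with zero Monte-Carlo sd
are flagged and excluded from the summary. If one chain truly generated the
pool, the Z collection is approximately standard normal; composition
heterogeneity inflates its spread.

*Dimer ANOVA.* Per-sequence fractions of the 10 collapsed dimer classes
(overlapping windows, N windows skipped) are subjected to a one-way ANOVA
across clusters: R² = SSB/SST with the F-test p-value; zero total variance
reports R² = 0, p = 1.

## Numerical and design choices

- Likelihoods are accumulated in log space everywhere (window scores,
  Bayes posterior via log-sum-exp) to avoid underflow at w ≥ 20 or L = 800.
- Determinism: argmax ties in F(S) break to the forward strand, then the
  smallest offset; candidate ties at equal p-value break to the
  lexicographically smallest core, then smallest source offset; Bayes ties
  are expected-accuracy weighted. Every stochastic routine takes a
  numpy Generator or an integer seed, and composite experiments derive
  per-cluster/per-run substreams from one root SeedSequence.
- Multi-width search pools the candidate families of all widths into a
  single BH correction, so widening the search pays its full
  multiple-testing price.
- The window trie stores only forward-strand windows; querying with the
  core and its reverse complement and taking the min halves memory at no
  cost by strand symmetry. Branch-and-bound abandons a path once its
  accumulated mismatches reach the current best. The bulk candidate
  pipeline uses an equivalent vectorized scan; trie, scan and a naive
  double loop are held equal on randomized instances in the tests.
- JASPAR PFM input accepts both the bracketed dialect and bare 4-row
  blocks (parsed via biopython); discovered PWMs are written in the
  bracketed dialect plus a TSV probability view. Coordinates are 0-based
  half-open internally and 1-based inclusive in outputs.
- Repeat masking is deliberately not applied; lower-case input is upper-
  cased on ingest.

## What the simulator does and does not emulate

The generator reproduces the *shape* of the yeast expression-cluster study:
~10–50 clusters of ≥10 sequences, 800 nt members, GC 0.4, one planted
motif of width ≥ 8 per cluster. It does not emulate repetitive elements,
composition heterogeneity across clusters (unless explicitly constructed,
as in the mixture diagnostics), nucleosome-related signals, multiple or
combinatorial motif occurrences, or phylogenetic conservation. Passing
tests on this synthetic data therefore demonstrates correctness of the
machinery and calibration under the stated generative model — not that the
discovery algorithms overcome the additional structure of real regulatory
DNA; measuring that gap on real data is what the benchmark protocol is for.

## Problem sizes used in the shipped experiments

The end-to-end experiments (test suite and `scripts/acceptance.py`) run at
desk scale, chosen once: 10 planted clusters of 30 sequences (length 800,
GC 0.4, width-10 peaked PWMs; discovery at w = 10, stride 2); FDR
calibration over 200 runs on a pool of 60 i.i.d. sequences of length 300
(clusters of 12, w = 8, stride 4); A/T diagnostics on 200 sequences with
B = 200 replicates, lengths 200–700 so per-length Monte-Carlo errors
decorrelate. On this scale the true-PWM upper bound lands around
0.87–0.88 mean holdout AUROC, the Bayes multiclass ceiling around 0.7–0.76
(against ~0.64 for the best-window plug-in classifier and 0.1 chance), the
LR benchmark shows a consistent resubstitution-over-holdout gap, and the
null rejection rate at q ≤ 0.05 stays at or below its nominal level —
numbers recomputed, not asserted, by `scripts/acceptance.py`.

## Known limitations

- Zero-or-one occurrence semantics: motif multiplicity within a sequence is
  not modeled, and no EM refinement is applied beyond the seed rule.
- Hamming distance only; no gapped or IUPAC-degenerate matching.
- Wilks' χ²₁ is asymptotic; with very small clusters (≲10 per side) the
  test can drift from nominal, which is why the calibration experiment is
  part of the acceptance surface.
- The A/T test assumes the fitted Markov model is estimated well enough
  that estimation noise is small relative to the heterogeneity being
  detected; for high orders on little data the Z spread mixes both.
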