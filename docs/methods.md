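# Methods

## Model overview

`pepsl` treats short conserved polypeptide segments — rather than annotated
domains — as the functional units through which synthetic lethal genetic
interactions (SLGIs) act.  The method has two halves: unsupervised discovery
of *short polypeptide clusters* from a proteome, and a probabilistic
interaction model over cluster pairs trained on known SLGIs.

### Window decomposition

Proteins are decomposed into overlapping windows of length `L = 25` residues
at step `w = 5`.  Windows are 0-based, half-open, and identified by
`(protein_id, start)`.  Proteins shorter than `L` contribute one full-length
window: real proteomes contain proteins down to ~16 residues, and dropping
them would silently shrink coverage.  Trailing residues not covered by the
last full window receive no extra tail window.

### Local alignment

Window pairs are scored with Smith-Waterman under BLOSUM62 and a **linear**
gap penalty of 14 per gap symbol.  Mismatch costs are taken from BLOSUM62
itself (that is what the matrix encodes); the single penalty value applies to
gap symbols only.  Symbols outside the matrix alphabet are scored through the
'X' column when the matrix has one, otherwise at a flat −1, so degenerate
residues never inflate a score.  Ties on the optimal score resolve to the
smallest `(query_end, subject_end)`; only the score feeds later stages.

Two implementations of the same dynamic program exist: a scalar aligner with
traceback, and batch kernels (a numpy scan formulation and a JIT-compiled
pairwise kernel used for all-vs-all matrices).  The test suite pins all of
them to each other and to Biopython's `PairwiseAligner` exactly.

### Significance calibration

For each window, the population of its scores against all windows of *other*
proteins (own-protein windows are excluded throughout) is summarized by a
Gumbel distribution via method of moments:

    beta = sigma * sqrt(6) / pi        mu = mean − 0.5772 * beta

with `sigma` the n−1 sample standard deviation.  Karlin–Altschul form
follows as `lambda = 1/beta`, `K = exp(mu/beta)/(m n)` with `m, n` the
lengths actually compared, so `E(S) = K m n exp(−lambda S)` and
`P = 1 − exp(−E)`.  The score threshold at a p-value `p` inverts these
exactly (`E* = −ln(1 − p)`, no small-p approximation):
`S_min = mu − beta ln E*`.  A window pair is a *reciprocal significant pair*
when its score reaches both windows' own `S_min` (`≥`, so analytically exact
threshold cases pass) at the default `p = 10⁻⁶`.  Windows whose population
has fewer than two scores or zero variance are skipped with a warning.

The moment fit assumes the population is **background-dominated**.  When a
substantial fraction of a window's scores come from genuinely homologous
windows, the fitted scale inflates and thresholds rise; this matters for
benchmark design (below) and for small inputs generally.  At realistic
proteome scale (hundreds of thousands of windows, families of tens of
members) the contamination is negligible.

### Cluster growth

Each significant pair seeds a cluster grown to a fixpoint:

1. progressive multiple alignment of the current members, guided by pairwise
   percent identity (closest pair first, then nearest member to the aligned
   set).  Pairwise and sequence-to-profile steps use the same BLOSUM62 /
   gap-14 scorer but with **free terminal gaps** (overlap alignment): members
   of one motif family are typically the same core sampled at different
   window phases, and penalized end gaps would misalign them;
2. per-column log-odds profile: `log(((count_r + 1)/(N + 20)) / (1/20))`
   with pseudocount 1 and uniform background, `N` the residues observed in
   the column; columns that are mostly gaps (> 50%) are dropped so the
   profile tracks the conserved core;
3. profile search of the whole catalog: every window is scored by its best
   ungapped profile placement, allowing shifts that keep at least half of the
   shorter side overlapping (again because of window phasing); the score
   population over the catalog is fitted with the same Gumbel machinery and
   converted to per-window E-values with `m` = profile length and `n` =
   window length; windows with `E ≤` the threshold join the cluster.

Membership only grows and is bounded by the catalog, so the iteration
terminates; a 100-iteration cap guards a hypothetical non-monotone search
adapter.  Growth is a pure function of the member set, so identical
intermediate states are memoized across seeds without affecting results.

The default hit threshold is `E = 10⁻⁵`, calibrated for this internal score
scale: on planted-family fixtures true members score around `E ~ 10⁻⁵–10⁻⁸`
while the best background window stays above `~10⁻²·⁵`.  Thresholds quoted
for external profile-HMM tools (10⁻¹⁰–10⁻²⁰) belong to a different score
scale and do not transfer; the threshold remains a configurable knob.

### Post-processing

Duplicate member sets collapse to one cluster.  Clusters are then merged
under one of three rules — any shared member, or shared members amounting to
at least 10% or 20% of the smaller cluster (integer arithmetic, so 1 shared
of 10 exactly meets the 10% rule).  Merging proceeds in rounds: evaluate the
rule on the current clusters, take connected components of qualifying pairs
(union-find), union their members, repeat until no pair qualifies.  Each
round is order-independent, hence so is the result; a strictly sequential
merge would not be, because merging can change the size of the smaller
partner in a fractional rule.  Finally, clusters with fewer than three
members are dropped (a two-member cluster cannot discriminate), and
optionally clusters spread over more than 20/50/100 proteins are dropped as
promiscuous.  The default configuration is the 10% merge with a 50-protein
filter.

### Interaction model and EM

Protein pairs and cluster pairs are linked by a deterministic-OR assumption:
two proteins interact iff at least one of their cluster pairs interacts,

    Pr(L_mn = 1) = 1 − Π_{i ∈ C(m), j ∈ C(n)} (1 − p_ij),

where cluster pairs are unordered and self-pairs `{i,i}` are allowed when a
cluster occurs in both proteins.  Estimation is EM over the hidden
cluster-pair interaction indicators:

* initialization: `M_ij` = number of known SLGI protein pairs containing
  `{i,j}`, `N_ij = 0`, `p_ij = M/(M + N + K)`;
* E-step: for each observed interacting pair, posterior
  `r_ij = p_ij / Pr(L_mn = 1)` accumulated into `M̂_ij = Σ r` and
  `N̂_ij = Σ (1 − r)` — sums run over the observed interacting pairs only,
  since under the OR model a non-interacting pair pins all its indicators to
  zero, which is exactly what the constant `K_ij` (count of non-interacting
  protein pairs containing `{i,j}`, over the universe of proteins that carry
  at least one cluster) contributes;
* M-step: `p_ij = (M̂ + a)/(M̂ + N̂ + K + a + b)` with pseudocounts
  `a = b = 1`, keeping every probability strictly inside (0, 1).

Convergence is monitored on the log of the complete-data likelihood
`Π p^{M̂+a} (1−p)^{N̂+K+b}` evaluated after each M-step (the raw product
underflows; the log is the equivalent stopping rule), with absolute
tolerance 10⁻⁶ and a 500-iteration cap.  The monitored quantity is the
maximized penalized expected complete-data log-likelihood; unlike the
penalized observed-data likelihood its monotonicity is not a theorem, but it
is non-decreasing (within 10⁻⁹) on every fixture in the test suite, which
the suite asserts.  A positive pair whose cluster-pair probabilities are all
zero contributes nothing for that iteration (logged); with pseudocounts this
state cannot persist.

Prediction applies the noisy-OR with trained `p_ij`; cluster pairs never
seen in training fall back to the pure-pseudocount value `a/(a+b) = 0.5`
(the M-step output for empty counts).  Protein pairs with no cluster pair
are **unscorable**, not probability 0 — the model has no evidence either
way, and coverage accounting reports them separately.  Evaluation uses the
Mann–Whitney (midrank) AUC.  For train/test hygiene the splitter removes
test pairs from the training positives (disjoint pair split, stratified by
label when negatives are present).

## Synthetic data

`pepsl.simulate` generates what the pipeline assumes about real data:
i.i.d. background residues (uniform composition by default — a composition
table is accepted; uniform keeps the extreme-value fit and false-positive
analysis clean), protein lengths from a truncated normal with mean 450,
sd 380, clipped to [16, 4901] (matching a real proteome's marginals without
claiming its distribution family), and `~25`-residue motif families planted
at random non-overlapping offsets with i.i.d. point substitutions.  Offsets
are deliberately *not* aligned to the window grid, so window phasing is
exercised.  SLGI labels are sampled from the same noisy-OR model the
predictor assumes, over planted family-pair probabilities; a separate
assignment generator produces protein→feature maps directly for EM-only
benchmarks.  Everything is a pure function of (parameters, seed).

What the generator does **not** emulate: realistic residue composition and
its effect on alignment statistics, insertions/deletions within motif
copies, paralogous domain architectures, and any biological structure in the
interaction network beyond the noisy-OR.  Passing benchmarks therefore
demonstrate correctness and calibration of the method under its own model
assumptions, not performance on real proteomes.

## Benchmark design and problem sizes

The benchmark suite (tests and `scripts/acceptance.py`) runs at desk scale,
chosen so that one full run fits in minutes on a single CPU while staying in
the regime the calibration assumes:

* **Clustering benchmark**: 200 proteins (background length mean 110, sd 30,
  clipped [60, 250]) with 10 planted families × 6 copies at 10%
  substitution — about 3,600 windows.  All-vs-all alignment is quadratic in
  window count, and per-window score populations must remain
  background-dominated, which couples family size to catalog size: ~150
  family-related windows among ~3,600 keeps the contamination of each
  fitted scale small while 30-copy families at this catalog size would
  swamp it.  Recovery is scored as pairwise precision/recall of final
  clusters against planted labels, where a window is labeled with a family
  when it overlaps a planted copy by ≥ 21 of 25 residues (the windows that
  essentially *are* the copy; a strict majority rule, so labels are unique).
* **EM benchmark**: 500 proteins, 50 clusters, planted probabilities drawn
  from {0, 0.2, 0.4, 0.6, 0.8} with weights {0.8, 0.05×4}; recovery RMSE is
  measured over cluster pairs supported by ≥ 5 protein pairs.
* **End-to-end benchmark**: the clustering fixture's true family pairs get 6
  "hot" pairs at p* = 0.8, labels are sampled, pairs are split 50/50, EM is
  trained on the training positives and evaluated by AUC on scorable
  held-out pairs.  The chance control is the mean AUC over 20 label
  permutations (a single permutation has standard error ≈ 0.03 at this test
  size).

## Numerical and implementation notes

* Score matrices are integer; batch kernels use int32 with a large negative
  padding score so padded positions can never align.
* The in-row DP dependency is vectorized as a running max:
  `H[i,j] = max_k≤j (t_k − g(j−k)) = max-accumulate(t + g·k) − g·j`.
* Degenerate profile-score populations (zero variance) freeze the growing
  cluster rather than abort the run; per-seed failures in batch clustering
  are logged and skipped.
* Merging uses exact integer comparisons (`shared·10 ≥ |smaller|`), avoiding
  float thresholds.
* All randomness flows through `numpy.random.default_rng` seeds; benchmark
  drivers derive stage seeds from one master seed.

## Known limitations

* The moment-based Gumbel fit is not robust to heavy homology contamination
  of a score population; very small catalogs with large families produce
  inflated thresholds (at full proteome scale the contamination is
  negligible by construction).
* Profile search is ungapped (windows are short and substitution noise is
  the dominant variation); families with internal indels would need the
  external profile-tool adapter seam.
* The interaction model ignores essentiality and any non-OR epistasis
  structure.
* Maximum-likelihood Gumbel fitting and composition-adjusted alignment
  statistics are out of scope; the method-of-moments estimators are the
  model.
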