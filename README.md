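# pepsl — short-polypeptide clusters and synthetic-lethality prediction

`pepsl` predicts **synthetic lethal genetic interactions (SLGIs)** between
proteins from their amino-acid sequences alone.  An SLGI is a pair of
individually non-essential genes whose double knockout is lethal; mapping
them experimentally is expensive, and sequence-only prediction is attractive
because it needs no other genome-wide data.  Classical "domain pair" models
are limited by domain annotation coverage, so `pepsl` instead builds its own
sequence features: *clusters of short polypeptides* — conserved ~25-residue
segments shared across proteins — and treats a cluster pair the way a domain
pair is treated in domain-interaction models.

The pipeline:

1. **Windows.** Each protein is chopped into overlapping peptide windows of
   length `L = 25` with step `w = 5` (proteins shorter than `L` keep one
   full-length window).
2. **Significant pairs.** Every window is Smith-Waterman aligned (BLOSUM62,
   linear gap penalty 14) against all windows of other proteins.  Each
   window's score population is fitted with a Gumbel/extreme-value
   distribution, `β = σ√6/π`, `μ = X̄ − 0.5772β`, converted to
   Karlin–Altschul form `λ = 1/β`, `K = e^{μ/β}/(mn)`, so a score `S` has
   `E = K·m·n·e^{−λS}` and p-value `P = 1 − e^{−E}`.  A window pair is kept
   only if its score is significant (default `p ≤ 10⁻⁶`) under **both**
   windows' own thresholds (reciprocal significance).
3. **Clusters.** Each significant pair seeds a cluster that is grown to a
   fixpoint: progressive multiple alignment of the members → position-specific
   log-odds profile → profile search of the whole window catalog (E-values
   calibrated by the same extreme-value machinery) → add hits, repeat until no
   window is added.  Clusters are then deduplicated, merged (share ≥1 member,
   or ≥10% / ≥20% of the smaller cluster), and filtered (fewer than 3 members,
   or present in more than 20/50/100 proteins).
4. **Interaction model.** With cluster content `C(m)` per protein, protein
   pairs interact under a noisy-OR over their cluster pairs:
   `Pr(L_mn = 1) = 1 − Π_{i∈C(m), j∈C(n)} (1 − Pr(C_ij = 1))`.
   The cluster-pair probabilities are estimated from known SLGIs by EM with
   pseudocounts `a = b = 1`:
   E-step `r_ij = p_ij / Pr(L_mn = 1)` summed over observed interacting
   pairs into expected counts `M_ij`, `N_ij`; M-step
   `p_ij = (M_ij + a)/(M_ij + N_ij + K_ij + a + b)` where the constant
   `K_ij` counts non-interacting protein pairs containing the cluster pair.
   Ranked noisy-OR probabilities predict new SLGIs; ROC/AUC evaluates them.

A synthetic-data module generates proteomes with planted motif families and
SLGI networks sampled from the same noisy-OR model, so the whole method is
testable without any external downloads.

## Worked example (CLI)

```
$ pepsl simulate --n-proteins 120 --families 6 --copies 6 --mut 0.1 \
        --length-mean 110 --length-sd 30 --seed 5 --out-prefix sim_
120 proteins, 6 families, 74 SLGIs -> sim_*

$ pepsl chop --fasta sim_proteome.fasta --out windows.tsv
1979 windows from 120 proteins -> windows.tsv

$ pepsl find-pairs --windows windows.tsv --out pairs.tsv
56 significant pairs -> pairs.tsv

$ pepsl cluster --pairs pairs.tsv --windows windows.tsv --merge frac10 \
        --max-proteins 50 --out clusters.tsv --assignment-out assignment.tsv
6 clusters -> clusters.tsv

$ pepsl train-em --interactions sim_interactions.tsv --clusters clusters.tsv \
        --out model.tsv
EM: 15 iterations, converged=True, loglik=-129.8022 -> model.tsv
```

The six planted motif families come back as six clusters.  The trained model
table (`cluster_i, cluster_j, M, N, K, p`) ranks cluster pairs by their
estimated interaction probability; the strongest learned pair here is

```
P0021:20  P0022:65   M=29.59  N=0.41  K=5   p=0.827
```

i.e. the EM attributes ~30 observed SLGIs to this cluster pair and estimates
an 83% interaction probability.  Predictions for candidate protein pairs are
noisy-OR combinations of these entries:

```
$ pepsl predict --model model.tsv --clusters clusters.tsv \
        --pairs candidates.tsv --threshold 0.5 --out pred.tsv
2 scored, 2 unscorable -> pred.tsv

protein_a  protein_b  probability  flagged
P0008      P0073      0.267836     0
P0008      P0076      0.267836     0
```

Pairs whose proteins share no cluster pair are reported *unscorable* rather
than probability zero — the model is silent about them.

The same stages are available as a library
(`pepsl.chop_proteome`, `pepsl.find_significant_pairs`,
`pepsl.clustering.cluster_all`, `pepsl.em.run_em`, …); see
`pepsl.pipeline.discover_clusters` for the one-call version.

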