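# Methods

## Model overview

`comorbnet` treats comorbidity prediction as transductive scoring on a signed
graph. The pipeline has three stages:

1. **Network construction.** PheWAS summary statistics are reduced to a sparse
   disease×SNP z-score matrix R (z = β/SE over associations passing the
   significance threshold), and every disease pair receives the signed cosine
   similarity of its z-score rows. The numerator runs over the SNPs stored for
   both diseases; the denominators are the Euclidean norms of each disease's
   own stored z-vector. Because absent entries are zero, this is exactly the
   cosine similarity of the sparse rows, so |w_ij| ≤ 1 by Cauchy–Schwarz.
   Pairs sharing no SNP get weight 0 (no edge).

2. **Propagation.** A unary label vector y (+1 on the index disease) is
   smoothed by minimizing (f−y)ᵀ(f−y) + μ fᵀL̄f with the signed Laplacian
   L̄ = D̄ − W, d̄_i = Σ_j |w_ij|. The smoothness term is
   Σ_{i~j} |w_ij| (f_i − sign(w_ij) f_j)², i.e. scores are pulled *together*
   across synergistic edges and *apart* across antagonistic ones. L̄ is
   positive semidefinite, so the objective is strictly convex and
   f = (I + μL̄)⁻¹y is unique.

3. **Evaluation and prioritization.** Against a binary patient×phenotype
   cohort, a disease is a true comorbid partner of the index disease when
   φ > 0 and RR > 1 of their 2×2 contingency. Scores are evaluated by ROC AUC
   and by Spearman ρ against RR, split at Youden's J into direct (f ≥ J) and
   inverse (f < J) sets, and stratified into deciles (Tier 1 highest scores,
   Tier 10 lowest).

## Conventions and numerical choices

- **Signed degrees.** The smoothness form is only positive semidefinite with
  absolute-value degrees d̄_i = Σ|w_ij|; that convention is used throughout
  (the W ≥ 0 special case reduces to the ordinary Laplacian, and the
  propagation then equals classic label propagation — asserted as a test).
- **Diagonal.** W has a zero diagonal: self-loops add a constant to both
  sides of the smoothness term and carry no information. A diagnostic
  `pair_similarity(R, i, i)` returns the cosine self-similarity 1.
- **Exact-zero cancellation.** A pair with shared SNPs whose mixed-sign
  products sum to exactly zero yields no edge; a cancellation counter is
  logged (float cancellation to exactly 0.0 is measure-zero in practice).
- **Zero-norm rows.** A disease with no stored SNPs is an isolated node; its
  similarities are defined as 0 and logged, never NaN.
- **Solvers.** Dense symmetric (Cholesky-backed) solve up to 2000 nodes;
  above that, Jacobi-preconditioned conjugate gradients with relative
  tolerance 1e-8, failing loudly with the residual on non-convergence.
  I + μL̄ has eigenvalues ≥ 1, so CG converges quickly; direct and iterative
  answers agree to ≤ 1e-6 on random graphs (tested).
- **μ default 1.0** (dimensionless loss/smoothness trade-off). The value is
  not critical for ranking on well-separated structure; `mu_sweep` provides a
  sensitivity sweep over {0.1, 0.5, 1, 2, 10}.
- **Rescaling.** Reported scores divide the unlabeled entries by their
  maximum absolute value, mapping them into [−1, 1] with the top-ranked
  unlabeled disease at ±1; the index disease is excluded from the maximum and
  keeps its raw score. Rescaling is strictly monotone, so AUC, Youden's J
  confusion counts, ranks and ρ are unchanged (tested).
- **Youden threshold.** Candidate cutoffs are the observed scores with rule
  f ≥ t → direct; ties in J break toward the smallest threshold (the most
  inclusive direct set).
- **Tiers.** Deciles by descending score; when the count is not divisible by
  10 the remainder goes to the *top* tiers (conservative: the direct group is
  never understated), and ties keep a stable order by phenotype id.
- **RR confidence interval.** The point estimate RR = C·N/(P_i·P_j)
  is paired with a Katz-type log-scale interval exp(ln RR ± 1.96·SE),
  SE² = 1/C − N/(P_i·P_j), clamped at 0 when negative (the interval then
  degenerates to the point estimate). The function is isolated so another
  interval method can be swapped in.
- **Undefined measures.** φ and RR are undefined at zero or full prevalence;
  such diseases are excluded from evaluation and counted, never crashed on.
  For all valid counts sign(φ) = sign(RR−1) — both share the numerator
  C·N − P_i·P_j — verified exhaustively for cohorts of up to 30 patients.
- **Spearman P-values.** Large-sample t approximation (scipy); an exact
  permutation P is available for n ≤ 8.
- **LD pruning.** Sliding window (50 kb, step 5 kb) per chromosome; within a
  window, for each pair with r² > 0.5 the variant with the larger minimum
  P-value across phenotypes is removed (keeping the most informative variant;
  ties removed at the larger position). r² comes from a user-supplied lookup;
  unknown pairs are treated as independent. Variants are sorted internally,
  so the result is order-invariant.
- **Filters.** Significance is strict (P < α); the case-count rule keeps
  n_cases ≥ 1000; category exclusions default to injuries & poisonings and
  symptoms (sex-specific categories are supplied by the user, since they are
  a property of the phenotype dictionary in use). Unparseable rows are
  skipped and counted, never coerced.

## Synthetic data: what it emulates and what it does not

The generator plants the causal structure the method is designed to detect.
Diseases fall into `n_clusters` contiguous clusters; every within-cluster
pair shares `shared_snps_within_cluster` SNPs whose effect signs agree with
probability `concordance_within` (default 0.9), and every between-cluster
pair shares `shared_snps_between_clusters` SNPs agreeing with probability
`concordance_between` (default 0.1). Each disease also carries private SNPs.
z-magnitudes are folded-normal around `effect_size_mean` (default 5), so
planted associations almost surely clear P < 1e-4; SE is log-uniform in
[0.01, 0.2], β = z·SE, and P is the two-sided normal tail — so the emitted
table is internally consistent and survives the package's own filters.
Simulated phenotype metadata reports case counts of the (much larger)
discovery PheWAS cohort, separate from the validation cohort below.

The matched cohort uses a sequential-conditional model: per patient, diseases
are visited in random order, and disease i occurs with
logit = logit(base_prevalence) + Σ_{j present} log(boost) for synergistic
planted pairs and log(damp) for antagonistic ones (defaults 0.05, 3.0, 1/3;
20 000 patients; 30 diseases). One global seed drives both stages through
independent derived streams, so each stage is reproducible on its own.

What this does *not* emulate: real LD between SNPs (positions are spaced
100 kb apart, so pruning is a no-op on synthetic data), the PheCode
hierarchy, realistic prevalence spectra, winner's-curse effect-size
inflation, or a calibrated joint disease model (the sequential-conditional
sampler realizes the intended RR directions but is not an Ising/loglinear
fit). Passing tests therefore show the pipeline recovers planted directional
structure under clean signal — not that it attains any particular accuracy
on biobank data.

## Design choices where the design was open

- The unsigned baseline defaults to `abs_cosine` (the similarity applied to
  |z|), which isolates the effect of *signs* while keeping magnitudes; the
  shared-SNP-count baseline from the earlier literature is provided as
  `shared_count`.
- Benchmark problem sizes (30 diseases, 20 000 patients, 20 replicates, 30
  recovery seeds) were chosen as the smallest study at which the planted
  structure is estimated stably (pair-count Monte-Carlo error on RR well
  inside the boost/damp effect).
- The propagation core is exposed as a scikit-learn estimator
  (`SignedLabelPropagation`) and the network construction as a transformer
  (`SignedNetworkBuilder`), so both compose with sklearn model selection;
  the module-level functions are thin wrappers.

## Known limitations

- Transductive only: scoring a disease absent from the network requires
  rebuilding the matrix.
- The φ/RR ground truth treats the cohort as cross-sectional co-diagnosis;
  no temporal ordering, age/sex adjustment or multiple-testing correction
  across index diseases is applied.
- Genotype-level r² computation and ICD→PheCode mapping are out of scope;
  both enter as precomputed inputs.
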