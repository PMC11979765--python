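# Methods

This note records the models, numerical choices and open design decisions
behind `grnval`, and what the synthetic-data tests do and do not establish
about behavior on real data.

## Hypergeometric enrichment

All gene-set tests reduce to the exact upper tail P(X ≥ x) of
X ~ Hypergeometric(N, m, k) (the `phyper(q = x − 1, …, lower.tail = FALSE)`
convention). The tail is an explicit sum of PMF terms from x to min(m, k),
each term evaluated in log space via log-gamma and combined with
log-sum-exp: with gene universes of ~30,000 and strong enrichments the tail
can fall below 1e-250, far outside naive factorial arithmetic but exactly
representable this way down to the double-precision floor (~1e-308). No
normal approximation is used anywhere. Inconsistent parameter combinations
(x > min(m, k), m > N, k > N) are rejected as errors rather than clamped —
silent clamping hides upstream bookkeeping bugs.

Fold enrichment is observed/expected, x / ((k/N)·m). One ambiguity worth
documenting prominently: a left-to-right reading of the printed formula
"x/(k/N) × m" would be x·N·m/k, which is not a fold enrichment; the
observed/expected reading is used.

Because the statistic is discrete, null p-values are sub-uniform: the
p-value CDF satisfies P(p ≤ p_x) = p_x only at attainable values and lies
below the diagonal between them. With m ≈ 400 predicted targets and
k ≈ 100 DEGs in a 5,000-gene universe the largest point mass (~0.15)
exceeds the two-sided KS critical value at n = 500, so *any* exact
implementation fails a two-sided uniformity KS. Validity is therefore
checked one-sided: no excess of small p-values (D⁺ statistic), which is
the property that matters for error control.

## Differential expression engine

A deliberately simplified NB Wald test in the DESeq2 mold, fully
vectorized across genes:

1. **Size factors**: median of ratios to the per-gene geometric-mean
   reference, genes with any zero excluded, factors rescaled to geometric
   mean 1. No pseudo-reference fallback — an input where no gene is
   nonzero in all samples is an error.
2. **Dispersion**: per-gene method of moments pooled across both groups
   after removing group means (Var(y/s) ≈ μ·mean(1/s) + α·μ²), then
   **moderated** toward a robust mean–dispersion trend α(μ) = a₀ + a₁/μ
   (iteratively reweighted least squares on the positive raw estimates) as
   the weighted average (d·α̂ + d₀·α_trend)/(d + d₀) with residual df d and
   prior weight d₀ = 10.
3. **Fit**: per-gene NB GLM log μ_ij = log s_j + b₀ + b₁·x_j by IRLS with
   Fisher weights μ/(1 + αμ); Wald statistic b₁/SE(b₁).
4. **Reference distribution**: t with df = residual + prior df (= 14 at
   3v3), the moderated-t of the limma tradition.
5. **Calls**: BH across the genes actually tested; up iff fdr < 0.05
   (strict) and log2fc ≥ 1 (inclusive), down mirrored. The fold-change
   rule is a post-hoc filter, not a composite null.

Why moderation: at 3 vs 3 replicates the raw moment estimator has ~4 df.
Plugging it into a normal-reference Wald test rejects ~12% of null genes
at nominal 5%; referring the same statistic to t(4) restores calibration
but its polynomial tails cap attainable p-values (p ≈ 2e-3 even at z = 7),
so no strongly perturbed gene survives BH over 5,000 genes. Neither
extreme can satisfy both calibration and power; trend moderation with a
moderated-t reference satisfies both (measured here: null rejection
5.0–5.3% at p < 0.05, ≥ 99% recovery of 4-fold changes at mean 500 and
dispersion 0.05, empirical FDR ≈ 1–2% among calls). Conformance note:
calls can differ from DESeq2 proper near the significance and fold
thresholds (no Cox-Reid adjustment, no MAP fold-change shrinkage, no
outlier handling); the simplification is intentional and documented.

Degenerate inputs: genes all-zero across both groups are dropped before
testing (the BH family is the tested genes); coefficient updates are
clipped to |b₁| ≤ 20 and linear predictors to ±30 so one-group-zero genes
stay finite; failed fits (singular information) report p = 1.

## Filters around the DE calls

- **Expressed filter**: CPM ≥ 1 (inclusive) in ≥ 1 sample of the tissue,
  mutant and control pooled.
- **Artifact filter**: genes DE in strictly more than half of the
  qualifying alleles are removed everywhere — recurrent DE across
  unrelated mutants reflects control-line genetic differences, not TF
  regulation. Which alleles qualify is an explicit argument (the study
  restricted to tissues where no single TF dominated the mutant read
  share, a bookkeeping fact the caller owns).
- **Ortholog filter**: only genes with a unique 1-to-1 W22/B73 gene-model
  pairing survive, since the predictions live in B73 coordinates.
- **Boundary conventions**: fdr exactly 0.05 is not significant ("< 0.05"
  strict); log2fc exactly ±1 is ("minimum fold change of 2" inclusive).

## Loss-of-function classification

An allele is loss-of-function iff every assembled transcript fragment
fails to encode a functional product: a 5′ fragment fails when its initial
AUG is out of frame; a 3′ fragment fails when it would encode strictly
less than half the normal protein (fraction 0.50 is not a failure). A
single rescuing fragment makes the allele not-LOF.

## Overlap between independent alleles

For each direction separately: expected shared DEGs n_a·n_b/universe,
representation factor shared/expected, p from the hypergeometric tail
(x = shared, m = n_a, k = n_b, N = expressed universe), significant iff
RF > 1 **and** p < 0.05 jointly. "Possible" shared DEGs is min(n_a, n_b)
within the direction; whether the source analysis took the minimum per
direction or across directions is ambiguous — per-direction is
implemented, the alternative noted here.

## Motif scanning

IUPAC consensus → position probability matrix: fixed letters carry
1 − 3ε with ε = 0.001 on the other bases (pure 0/1 columns would give
infinite log-odds); degenerate codes split mass uniformly; N takes the
genomic composition p(G) = p(C) = gc/2, p(A) = p(T) = (1 − gc)/2. The
background is that same GC-derived 0-order model — *not* re-estimated
from the scanned sequences — so a scan is a pure function of
(consensus, gc, threshold) and deterministic.

Per-position log2-odds are rounded onto an integer lattice (default 1,000
bins across the score range) and the exact distribution of the lattice
total under the background is built by dynamic-programming convolution.
Scanner and distribution share the lattice, so a reported p-value is the
*exact* tail probability of the score the scanner assigned — verified
against full 4^L word enumeration for short motifs. Refining the lattice
10× moves p-values by < 1e-3 relative. Hits are windows with p ≤ 0.01
(inclusive, FIMO's convention); windows containing non-ACGT letters are
skipped; minus-strand windows are scored on the reverse complement with
coordinates always reported on the forward strand, BED-style 0-based
half-open. Genome-wide scanning then BED subsetting and direct scanning
of extracted regions give identical within-region hits.

One subtlety: the generic HSF consensus NGAANNTTCN is reverse-complement
palindromic, so every plus-strand hit recurs identically on the minus
strand. False-positive calibration against a binomial expectation must
therefore count per-strand windows as the independent trials (the
two-strand count has exactly twice the variance); the acceptance checks
do this, and compare against the *attained* size of the discrete test
(the largest tail value ≤ 0.01) rather than 0.01 itself.

Interval intersection keeps hits overlapping ≥ 1 bp with any cloned
region (half-open abutment is no overlap), via an interval tree; tests
compare against a naive all-pairs oracle.

## Metabolite pipeline

Per compound per batch, LOD = 3 × mean blank peak area. Below-LOD status
is assessed on the raw peak-area scale against the sample's own batch LOD
— the blank-derived LOD has no meaningful sample weight, so comparing
weight-normalized AUA against it would mix units; AUA (area / dry weight,
mg) is used for all statistics instead. This resolves an ambiguity in the
source description and is flagged as a deliberate choice. A sample value
is *missing* (NaN) or, failing that, *below LOD*; a compound is removed
when strictly more than 10% of pooled non-blank samples are missing, or
strictly more than 20% are below LOD. Missing values are never imputed.
Technical replicates are averaged to one biological-replicate AUA before
testing. Control consistency: compounds with control-A vs control-B
fdr < 0.05 (Welch t on log2 AUA, BH across compounds) are removed so
control-line differences cannot masquerade as mutant effects. Mutant
effects: per compound, mutant vs each control, BH within each
mutant-vs-control family; significant only when fdr < 0.05 against both
controls with agreeing sign. The BH families (per comparison for mutants,
across compounds for the control test) are the narrowest defensible
choices and are recorded in the outputs.

## Trait rules

Heights: log2-transform, Welch t of each mutant row vs the pooled control
rows, BH across mutant rows within one field, fdr < 0.05; comparisons
never cross fields. The Welch flavor is a choice — the source says only
"unpaired" — and is switchable (`equal_var=True`). Flowering time has one
value per row, so no test: flagged iff |mutant − control mean| > 3 days,
strictly, per field.

## Synthetic-data generator

The generator is first-class, tested code; its defaults *are* the study
conditions at desk scale: 5,000 genes, 2 TFs × 2 independent alleles,
3 biological replicates, 400 predicted targets per TF over 45 networks of
which a quarter (100) are truly perturbed at 4-fold (half up, half down),
100 allele-specific off-target DEGs, NB dispersion 0.1, per-gene baseline
means log-normal(log 200, 1), per-sample size factors log-uniform in
[0.7, 1.4], TF self-knockdown to 0.25×; 100 promoters of 1 kb at GC 0.47
with the HSF site planted in half; 31 compounds in 2 LC-MS batches with
3 blanks each, 2 designed below-LOD compounds, 1 designed-missing, 4
control-line-different, 2 with a −2 log2 mutant effect, technical
replicates duplicating 20% of batch-1 samples; 12 trait mutants vs 11
control rows in 2 fields. Every sub-generator owns a PCG64 stream derived
from the master seed through a fixed spawn key, so outputs are
bit-identical under a seed and adding a generator never perturbs others.

Two deliberate departures from full i.i.d. sampling, both in the
metabolite generator and both reversible with `iid_noise=True`:

- **Replicate-matched noise.** Replicate-level noise and sample weights
  are realized once per compound/replicate index and shared across
  genotypes, so a genotype contrast equals its designed effect exactly
  (null contrasts are exactly zero). Rationale: the compound accounting
  (31 → 28 → 24) is a fixture-exactness check of the filter logic; under
  i.i.d. noise the control-vs-control BH step has an irreducible ~19%
  per-seed chance of one of ~24 null compounds landing below the
  threshold (the null p-value is uniform regardless of how small the
  noise is), which would make an exact accounting test meaningless.
  Statistical calibration of the tests themselves is established
  separately on i.i.d. data.
- **Exact technical duplicates.** Tech reps carry no added technical
  variance by default; the averaging path is exercised structurally, and
  unit tests build their own noisy tech reps.

What passing the synthetic suite does *not* show about real data: the
generator draws genes independently (no correlation structure, no batch
or library-preparation artifacts beyond scalar size factors), promoter
background is 0-order i.i.d. (real promoters have repeats and
compositional heterogeneity that inflate motif false positives), LC-MS
noise is log-normal with no retention-time or carry-over structure, and
dispersion follows the same NB family the DE engine assumes — so the DE
calibration results certify the inference machinery, not robustness to
model misspecification.

## Problem sizes and runtime

Calibration and recovery checks run at the study scale the conditions
define: 5,000-gene matrices at 3v3 (one null dataset for the rejection
rate; 50 planted datasets for empirical FDR; 10 seeds for enrichment
recovery; 500 decoy prediction draws for the null p-value check; 100
promoters for planted-site recovery and false-positive control; 500 draws
for the representation-factor null mean). The determinism check reruns
the full pipeline at a reduced 1,200-gene scale, which exercises every
stage and file format identically. The whole acceptance script completes
in well under a minute on one CPU.
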