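# grnval

Reverse-genetics validation of gene-regulatory-network (GRN) predictions.
Computational predictions of transcription-factor (TF) targets — from gene
co-expression networks (GCNs) and yeast one-hybrid (Y1H) promoter-binding
assays — are only hypotheses until a TF is knocked out and its predicted
targets actually change expression. `grnval` implements the statistical
pipeline for that test, built around maize UniformMu TF mutants but generic
in structure, and ships a synthetic-study generator with planted ground
truth so every stage is verifiable without any external data.

## What it computes

**Differential expression per mutant allele.** From an integer count matrix:
CPM ≥ 1 expressed-gene filter per tissue, median-of-ratios normalization, a
per-gene negative-binomial Wald test of mutant vs control (dispersion by
method of moments, moderated toward a mean–dispersion trend; moderated-t
reference), BH adjustment, and the call rule FDR < 0.05 with |log2fc| ≥ 1.
Genes DE in more than half of all mutant alleles are removed as control-line
artifacts, and DEG lists are restricted to genes with 1-to-1 W22/B73 gene
models.

**Gene-set statistics.** All enrichment uses the exact hypergeometric upper
tail, P(X ≥ x) for X ~ Hypergeom(N, m, k), computed by log-gamma summation
(the `phyper(q = x − 1, m, n = N − m, k, lower.tail = FALSE)`
parameterization), with fold enrichment x / ((k/N)·m):

- GCN predicted-target enrichment at the n1 (≥1 network) and n3 (≥3 of 45
  networks) support thresholds: N = expressed nonredundant predicted
  targets, m = expressed predicted targets of the TF, k = DEGs, x = DEGs
  that are predicted targets.
- GO term over-representation on up- and down-regulated sets.
- Cross-allele overlap: expected shared DEGs = n_a·n_b/universe,
  representation factor = observed/expected, significant iff RF > 1 and
  P < 0.05; the "possible" overlap is min(n_a, n_b) per direction.
- Y1H targets classified as up / down / not DE / untested (unannotated or
  not expressed).

**Promoter motif scanning.** A FIMO-style scanner for degenerate consensi
(e.g. the generic HSF site `NGAANNTTCN`), N positions weighted by genomic GC
content; per-window log-odds scores on an integer lattice with the exact
null distribution computed by dynamic programming, hits at p ≤ 0.01
intersected with Y1H cloned-promoter BED regions (0-based half-open).

**Targeted phenolic metabolomics.** Batch-wise limits of detection (3× mean
blank peak area), weight normalization to arbitrary units of area (AUA),
technical-replicate averaging, removal of compounds >20% below LOD or >10%
missing, removal of compounds differing between the two W22 control lines,
and per-mutant dual-control t-tests on log2 AUA (significant only vs both
controls with agreeing sign).

**Field traits.** Log-scale t-tests of each mutant row vs pooled controls
within a field (BH within field), and the ±3-day flowering-time flag.

**Loss-of-function calls.** An allele is loss-of-function iff no assembled
transcript fragment can encode a functional product: 5′ fragments with the
initial AUG out of frame, 3′ fragments encoding < 50% of the protein.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (2 TFs × 2 independent alleles, 5,000 genes, 3 replicates, 400
predicted targets per TF of which 100 are truly perturbed 4-fold):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_call_de_genes.py
python analysis/03_test_target_enrichment.py
...
python analysis/07_summarize.py
```

The summary printed by `07_summarize.py` (seed 1):

```
allele tf_id  n_up  n_down  tf_log2fc  tf_significant    pvalue_n1  pvalue_n3  fold_enrichment_n1  overlap_significant
tf1-m1   TF1    88      90  -1.751853            True 8.347100e-20   0.000015            1.783807                 True
tf1-m2   TF1    87      88  -2.451561            True 1.694710e-26   0.000001            1.902339                 True
tf2-m1   TF2    92      75  -2.101427            True 1.989950e-19   0.001468            1.803490                 True
tf2-m2   TF2    95      80  -2.310773            True 4.297660e-19   0.002099            1.818752                 True
```

Reading it: each allele recovers ~175 DEGs of the ~200 planted (100 shared
TF targets + 100 allele-specific off-targets), the TF's own knockdown to
0.25× WT is estimated (log2fc near −2) and significant, the DEGs are
strongly enriched for the TF's predicted targets at both support
thresholds (p ≪ 0.05 against the predicted-target universe of N = 731),
and the two independent alleles of each TF share far more DEGs than chance
(representation factors > 20). The metabolite stage reproduces the
designed compound accounting 31 profiled → 28 past QC → 24 analyzable.

The same stages are available as a CLI (`grnval simulate|de|enrich|scan|
metab|traits|report|all`), each stage writing TSV/BED outputs and a run
manifest; reruns under the same seed and config are byte-identical.

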