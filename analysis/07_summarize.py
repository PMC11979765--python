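#!/usr/bin/env python
"""Join all stage outputs into the per-allele summary table (report.tsv):
DEG counts, TF self-knockdown, n1/n3 enrichment, cross-allele overlap,
Y1H target classes and metabolite effects per allele."""

import argparse

from grnval.io import PipelineConfig
from grnval.pipeline import stage_report

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", default="results/study")
args = parser.parse_args()

report = stage_report(args.outdir, PipelineConfig())
cols = [c for c in ["allele", "tf_id", "n_up", "n_down", "tf_log2fc",
                    "tf_significant", "pvalue_n1", "pvalue_n3",
                    "fold_enrichment_n1", "overlap_significant",
                    "y1h_up", "y1h_down", "y1h_not_de", "y1h_untested",
                    "n_metabolites_significant"] if c in report.columns]
print(report[cols].to_string(index=False))
print(f"\nfull table: {args.outdir}/report.tsv")
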