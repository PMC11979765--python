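#!/usr/bin/env python
"""Phenolic metabolite QC and mutant testing.

Batch-wise LODs from blanks (3x mean blank area), AUA normalization,
the >20% below-LOD / >10% missing compound filters, removal of compounds
differing between the two W22 control lines, and the dual-control t-tests
per mutant allele on log2 AUA.
"""

import argparse

from grnval.io import PipelineConfig
from grnval.pipeline import stage_metab

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", default="results/study")
args = parser.parse_args()

out = stage_metab(args.outdir, PipelineConfig())
qc = out["qc"]
n = len(qc)
kept = (qc["status"] == "kept").sum()
print(f"compound accounting: {n} profiled -> {kept} past QC -> "
      f"{len(out['analyzable'])} analyzable after control-consistency removal")
print(qc.groupby("status").size().to_string())
sig = out["tests"][out["tests"]["significant"]]
print("\nsignificant mutant effects (vs both controls):")
cols = ["mutant", "compound", "log2fc_a", "log2fc_b", "fdr_a", "fdr_b"]
print(sig[cols].to_string(index=False) if len(sig) else "(none)")
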