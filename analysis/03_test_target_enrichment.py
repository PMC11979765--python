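#!/usr/bin/env python
"""Test predicted-target enrichment and cross-allele DEG overlap.

Hypergeometric enrichment of each allele's DEGs for its TF's GCN-predicted
targets at the n1 (>=1 network) and n3 (>=3 networks) support thresholds,
GO over-representation, representation-factor overlap between independent
alleles of the same TF, and Y1H target classification.
"""

import argparse

from grnval.io import PipelineConfig
from grnval.pipeline import stage_enrich

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", default="results/study")
args = parser.parse_args()

out = stage_enrich(args.outdir, PipelineConfig())
enr = out["enrichment"]
both = enr[enr["direction"] == "both"]
print("GCN predicted-target enrichment (both directions):")
print(both[["tf_id", "allele", "prediction_set", "x", "m", "k", "N",
            "pvalue", "fold_enrichment", "significant"]].to_string(index=False))
print("\nShared DEGs between independent alleles per TF:")
print(out["overlap"][["tf_id", "direction", "n_a", "n_b", "shared",
                      "representation_factor", "pvalue", "proportion",
                      "significant"]].to_string(index=False))
y1h = out["y1h"].groupby(["tf_id", "status"]).size().unstack(fill_value=0)
print("\nY1H predicted-target classification (summed over alleles):")
print(y1h.to_string())
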