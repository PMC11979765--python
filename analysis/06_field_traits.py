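#!/usr/bin/env python
"""Field-trait comparisons: plant/ear height t-tests and flowering flags.

Per field environment: each mutant row vs the pooled W22 control rows on
log-transformed heights (BH across mutant rows within the field,
significant at FDR < 0.05); flowering time flagged when the single row
value differs from the control mean by strictly more than 3 days.
"""

import argparse

from grnval.io import PipelineConfig
from grnval.pipeline import stage_traits

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", default="results/study")
args = parser.parse_args()

out = stage_traits(args.outdir, PipelineConfig())
sig = out["tests"][out["tests"]["significant"]]
print("significant height differences:")
print(sig.to_string(index=False) if len(sig) else "(none)")
flagged = out["flags"][out["flags"]["flag"] == "flagged"]
print("\nflowering-time flags (> 3 days vs control mean):")
print(flagged.to_string(index=False) if len(flagged) else "(none)")
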