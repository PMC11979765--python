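#!/usr/bin/env python
"""Scan cloned promoter regions for the degenerate HSF binding site.

FIMO-style scan of the generic HSF consensus NGAANNTTCN (N weighted by
genomic GC content) at exact p <= 0.01, subset to the Y1H cloned-promoter
BED intervals, then checked against the planted sites recorded at
simulation time.
"""

import argparse
import json
from pathlib import Path

from grnval.io import PipelineConfig
from grnval.pipeline import stage_scan

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", default="results/study")
args = parser.parse_args()

hits = stage_scan(args.outdir, PipelineConfig())
truth = json.loads((Path(args.outdir) / "inputs" / "truth.json").read_text())
planted = truth["planted_sites"]
key = set(zip(hits["sequence_id"], hits["start"], hits["strand"]))
found = sum((sid, pos, strand) in key for sid, pos, strand in planted)
print(f"{len(hits)} hits within cloned regions across "
      f"{hits['sequence_id'].nunique()} promoters")
print(f"planted-site recovery: {found}/{len(planted)}")
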