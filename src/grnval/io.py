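"""Readers/writers for the pipeline's plain-text formats, plus run config.

TSV for counts, sample metadata, predictions, orthologs, GO annotations,
metabolite areas and traits; FASTA for promoter sequences (multi-line and
lowercase tolerated); BED3+ for cloned-promoter regions (0-based half-open,
start < end enforced). Every reader round-trips with its writer on
canonical files. Malformed cells raise errors that name the offending
row/column.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import CountMatrix
from .metabolomics import SAMPLE_COLUMNS, MetaboliteTable

__all__ = [
    "PipelineConfig",
    "read_counts", "write_counts",
    "read_samples", "write_samples",
    "read_predictions", "write_predictions",
    "read_orthologs", "write_orthologs",
    "read_go", "write_go",
    "read_metabolites", "write_metabolites",
    "read_fasta", "write_fasta",
    "read_bed", "write_bed",
    "load_config", "save_config",
]


@dataclass
class PipelineConfig:
    """Run-wide thresholds; defaults are the study's printed values."""

    seed: int = 1
    cpm_min: float = 1.0
    fdr: float = 0.05
    min_log2fc: float = 1.0  # minimum fold change of 2
    motif_p: float = 0.01
    lod_multiplier: float = 3.0
    lod_frac: float = 0.20
    missing_frac: float = 0.10
    rf_min: float = 1.0
    flowering_days: float = 3.0
    n3_support: int = 3
    consensus: str = "NGAANNTTCN"
    gc_content: float = 0.47

    def __post_init__(self) -> None:
        for name in ("cpm_min", "fdr", "min_log2fc", "motif_p", "lod_multiplier",
                     "lod_frac", "missing_frac", "flowering_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# count matrices


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        for col in counts.columns:
            bad = pd.to_numeric(counts[col], errors="coerce")
            if bad.isna().any():
                row = counts.index[bad.isna()][0]
                raise ValueError(
                    f"non-numeric count at gene {row!r}, sample {col!r} "
                    f"in {counts_path}"
                )
    frac = arr - np.floor(arr)
    if np.abs(frac).max() > 0:
        g, s = np.argwhere(np.abs(frac) > 0)[0]
        raise ValueError(
            f"non-integer count at gene {counts.index[g]!r}, "
            f"sample {counts.columns[s]!r} in {counts_path}"
        )
    samples = read_samples(samples_path)
    return CountMatrix(counts.astype(np.int64), samples)


def write_counts(matrix: CountMatrix, counts_path: str | Path,
                 samples_path: str | Path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t")
    write_samples(matrix.samples, samples_path)


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "genotype", "tissue", "replicate"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: sample metadata needs columns {sorted(need)}")
    return df.set_index("sample_id")


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# predictions / orthologs / GO


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"tf_id", "gene_id", "source", "support"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: predictions need columns {sorted(need)}")
    return df


def write_predictions(preds: pd.DataFrame, path: str | Path) -> None:
    preds.to_csv(path, sep="\t", index=False)


def read_orthologs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"w22_id", "b73_id", "one_to_one"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: ortholog map needs columns {sorted(need)}")
    df["one_to_one"] = df["one_to_one"].astype(bool)
    return df


def write_orthologs(mapping: pd.DataFrame, path: str | Path) -> None:
    mapping.to_csv(path, sep="\t", index=False)


def read_go(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    need = {"term_id", "gene_id"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: GO table needs columns {sorted(need)}")
    return {t: set(g["gene_id"]) for t, g in df.groupby("term_id")}


def write_go(go: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [
        {"term_id": t, "term_name": t, "aspect": "BP", "gene_id": g}
        for t in sorted(go)
        for g in sorted(go[t])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# metabolites


def read_metabolites(areas_path: str | Path, samples_path: str | Path) -> MetaboliteTable:
    areas = pd.read_csv(areas_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    need = set(SAMPLE_COLUMNS) | {"sample_id"}
    if not need <= set(samples.columns):
        raise ValueError(f"{samples_path}: needs columns {sorted(need)}")
    samples["is_blank"] = samples["is_blank"].astype(bool)
    return MetaboliteTable(areas, samples.set_index("sample_id"))


def write_metabolites(table: MetaboliteTable, areas_path: str | Path,
                      samples_path: str | Path) -> None:
    table.areas.to_csv(areas_path, sep="\t")
    table.samples.reset_index().to_csv(samples_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA / BED


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{i}: start {start} >= end {end} "
                    "(BED is 0-based half-open)"
                )
            out.append((chrom, start, end))
    return out


def write_bed(regions: Iterable[tuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        for region in regions:
            fh.write("\t".join(str(x) for x in region) + "\n")
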