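"""Targeted LC-MS phenolic pipeline.

Batch-wise limits of detection from blanks, weight normalization to
arbitrary units of area (AUA), technical-replicate averaging, the compound
QC filters (>20% of samples below LOD, or >10% missing), removal of
compounds that differ between the two W22 control lines, and the
dual-control significance test for each mutant allele.

Peak areas arrive already integrated (compound x sample); no imputation is
ever performed — a sample missing a compound simply drops out of that
compound's test. The below-LOD comparison is made on the raw peak-area
scale (the scale on which the blank-derived LOD lives; blanks carry no
meaningful sample weight), while all statistics run on log2 AUA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import bh_adjust, log_ttest

__all__ = [
    "MetaboliteTable",
    "compute_lod",
    "lod_table",
    "normalize_aua",
    "average_tech_reps",
    "filter_compounds",
    "control_consistency_filter",
    "dual_control_test",
]

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["genotype", "batch", "is_blank", "weight_mg", "tech_rep_group", "bio_rep"]


@dataclass
class MetaboliteTable:
    """Peak areas (compound rows x sample columns; NaN = missing) + metadata.

    ``samples`` is indexed by sample_id with columns genotype, batch,
    is_blank, weight_mg, tech_rep_group, bio_rep. Blanks (extraction solvent
    alone) need no genotype or weight; every non-blank sample must have a
    positive weight.
    """

    areas: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.areas.columns) != set(self.samples.index):
            raise ValueError("area columns and sample metadata rows disagree")
        missing_cols = set(SAMPLE_COLUMNS) - set(self.samples.columns)
        if missing_cols:
            raise ValueError(f"sample metadata lacks columns {sorted(missing_cols)}")
        nb = self.samples[~self.samples["is_blank"].astype(bool)]
        w = nb["weight_mg"].astype(float)
        if (w <= 0).any() or w.isna().any():
            bad = nb.index[(w <= 0) | w.isna()][0]
            raise ValueError(f"non-blank sample {bad!r} lacks a positive weight")
        self.samples = self.samples.loc[list(self.areas.columns)]

    def blank_ids(self, batch: int | None = None) -> list[str]:
        m = self.samples["is_blank"].astype(bool)
        if batch is not None:
            m &= self.samples["batch"] == batch
        return list(self.samples.index[m])

    def nonblank_ids(self) -> list[str]:
        return list(self.samples.index[~self.samples["is_blank"].astype(bool)])


def compute_lod(blank_areas: Sequence[float]) -> float:
    """LOD = 3 x mean blank peak area (one compound, one batch).

    An all-zero blank set yields a degenerate LOD of 0, flagged with a
    warning rather than an error (every real measurement then clears it).
    """
    arr = np.asarray(blank_areas, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no blank measurements in this batch")
    if (arr < 0).any():
        raise ValueError("blank peak areas must be non-negative")
    lod = 3.0 * float(arr.mean())
    if lod == 0.0:
        logger.warning("all-zero blanks: LOD degenerate at 0")
    return lod


def lod_table(table: MetaboliteTable) -> pd.DataFrame:
    """Per-compound, per-batch LODs from the batch's blank samples."""
    batches = sorted(table.samples["batch"].unique())
    out = {}
    for b in batches:
        blanks = table.blank_ids(batch=b)
        if not blanks:
            raise ValueError(f"batch {b} has no blank samples")
        out[b] = table.areas[blanks].apply(
            lambda row: compute_lod(row.to_numpy()), axis=1
        )
    return pd.DataFrame(out)


def normalize_aua(peak_area: float, weight_mg: float) -> float:
    """Arbitrary units of area: peak area / sample dry weight (mg)."""
    if weight_mg <= 0:
        raise ValueError(f"sample weight must be positive, got {weight_mg}")
    return peak_area / weight_mg


def aua_matrix(table: MetaboliteTable) -> pd.DataFrame:
    """AUA for every non-blank sample column."""
    cols = table.nonblank_ids()
    w = table.samples.loc[cols, "weight_mg"].astype(float)
    return table.areas[cols] / w


def average_tech_reps(table: MetaboliteTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse technical replicates to biological-replicate AUA.

    Returns (bio_aua, bio_meta): columns of ``bio_aua`` are tech_rep_group
    labels (one per biological replicate); the value is the mean AUA over
    the group's technical replicates (a singleton group passes through
    unchanged; a missing tech rep drops out of the mean).
    """
    aua = aua_matrix(table)
    meta = table.samples.loc[aua.columns]
    bio_aua = aua.T.groupby(meta["tech_rep_group"]).mean().T
    bio_meta = (
        meta.reset_index()
        .groupby("tech_rep_group")
        .agg(genotype=("genotype", "first"), batch=("batch", "first"),
             bio_rep=("bio_rep", "first"), n_tech=("tech_rep_group", "size"))
    )
    return bio_aua, bio_meta.loc[bio_aua.columns]


def filter_compounds(
    table: MetaboliteTable,
    lods: pd.DataFrame | None = None,
    lod_frac: float = 0.20,
    missing_frac: float = 0.10,
) -> pd.DataFrame:
    """Compound QC over the pooled samples of both batches.

    A sample value is *missing* if NaN, else *below LOD* if its raw peak
    area is below its own batch's LOD for that compound (a value is only
    ever one of the two; missing is evaluated first). A compound is removed
    when strictly more than 10% of samples are missing (``removed_missing``)
    or, failing that, strictly more than 20% are below LOD (``removed_lod``).
    Blanks are excluded from every denominator.
    """
    if lods is None:
        lods = lod_table(table)
    cols = table.nonblank_ids()
    sub = table.areas[cols]
    batches = table.samples.loc[cols, "batch"]
    n = len(cols)
    lod_per_sample = lods[batches].to_numpy()  # compound x sample, batch-matched
    vals = sub.to_numpy(dtype=float)
    is_missing = np.isnan(vals)
    below = (~is_missing) & (vals < lod_per_sample)
    frac_missing = is_missing.sum(axis=1) / n
    frac_below = below.sum(axis=1) / n
    status = np.where(
        frac_missing > missing_frac,
        "removed_missing",
        np.where(frac_below > lod_frac, "removed_lod", "kept"),
    )
    return pd.DataFrame(
        {
            "compound": sub.index,
            "frac_below_lod": frac_below,
            "frac_missing": frac_missing,
            "status": status,
        }
    ).reset_index(drop=True)


def _log2_group(
    bio_aua: pd.DataFrame, bio_meta: pd.DataFrame, genotype: str, compound: str
) -> np.ndarray:
    cols = bio_meta.index[bio_meta["genotype"] == genotype]
    v = bio_aua.loc[compound, cols].to_numpy(dtype=float)
    return v[~np.isnan(v)]


def control_consistency_filter(
    table: MetaboliteTable,
    control_a: str,
    control_b: str,
    compounds: Iterable[str] | None = None,
    fdr_threshold: float = 0.05,
) -> tuple[set[str], pd.DataFrame]:
    """Remove compounds that differ between the two W22 control lines.

    Per compound: unpaired t-test on log2 AUA of control A vs control B,
    BH across the tested compounds; removed iff fdr < 0.05. Removing these
    avoids calling mutant effects that are really control-line differences.
    """
    bio_aua, bio_meta = average_tech_reps(table)
    for c in (control_a, control_b):
        if (bio_meta["genotype"] == c).sum() < 2:
            raise ValueError(f"control group {c!r} needs >= 2 biological replicates")
    comps = list(compounds) if compounds is not None else list(table.areas.index)
    rows = []
    for comp in comps:
        a = _log2_group(bio_aua, bio_meta, control_a, comp)
        b = _log2_group(bio_aua, bio_meta, control_b, comp)
        if len(a) < 2 or len(b) < 2:
            logger.info("control test skipped for %s: <2 replicates", comp)
            continue
        res = log_ttest(a, b, base=2)
        rows.append({"compound": comp, "log2fc": res.effect, "pvalue": res.pvalue})
    out = pd.DataFrame(rows, columns=["compound", "log2fc", "pvalue"])
    if len(out):
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    else:
        out["fdr"] = pd.Series(dtype=float)
    removed = set(out.loc[out["fdr"] < fdr_threshold, "compound"])
    return removed, out


def dual_control_test(
    table: MetaboliteTable,
    mutant: str,
    controls: tuple[str, str],
    compounds: Iterable[str] | None = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Mutant vs both W22 controls on log2 AUA.

    Two unpaired t-tests per compound (mutant vs each control), BH within
    each mutant-vs-control comparison family. A compound is significant only
    when fdr < 0.05 against BOTH controls and the two effects share a sign.
    Reports the log2 fold change versus each control. Compounds with <2
    replicates in any group are skipped with a log entry.
    """
    bio_aua, bio_meta = average_tech_reps(table)
    comps = list(compounds) if compounds is not None else list(table.areas.index)
    rows = []
    for comp in comps:
        mvals = _log2_group(bio_aua, bio_meta, mutant, comp)
        res = {}
        ok = len(mvals) >= 2
        for tag, ctrl in zip(("a", "b"), controls):
            cvals = _log2_group(bio_aua, bio_meta, ctrl, comp)
            if len(cvals) < 2 or not ok:
                ok = False
                break
            t = log_ttest(mvals, cvals, base=2)
            res[f"log2fc_{tag}"] = t.effect
            res[f"pvalue_{tag}"] = t.pvalue
        if not ok:
            logger.info("dual-control test skipped for %s (%s): <2 replicates",
                        comp, mutant)
            continue
        rows.append({"compound": comp, **res})
    out = pd.DataFrame(
        rows, columns=["compound", "log2fc_a", "pvalue_a", "log2fc_b", "pvalue_b"]
    )
    if len(out):
        out["fdr_a"] = bh_adjust(out["pvalue_a"].to_numpy())
        out["fdr_b"] = bh_adjust(out["pvalue_b"].to_numpy())
        out["significant"] = (
            (out["fdr_a"] < fdr_threshold)
            & (out["fdr_b"] < fdr_threshold)
            & (np.sign(out["log2fc_a"]) == np.sign(out["log2fc_b"]))
        )
    else:
        for c in ("fdr_a", "fdr_b"):
            out[c] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    out.insert(0, "mutant", mutant)
    return out
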