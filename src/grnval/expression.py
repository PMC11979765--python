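"""Differential expression for TF loss-of-function mutant alleles.

From an integer count matrix to per-allele DE calls with the filters the
study design prescribes: expressed-gene CPM filter, negative-binomial Wald
test per gene, BH adjustment, the 2-fold + FDR < 0.05 call rule, removal of
genes consistently DE across most alleles (control-line artifacts), and the
1-to-1 W22/B73 ortholog filter. Also: the TF's own expression change and the
loss-of-function call from assembled mutant transcript fragments.

The DE engine is a deliberately simplified DESeq2-style test: median-of-ratios
size factors, per-gene method-of-moments dispersion moderated toward a robust
mean-dispersion trend, a vectorized IRLS NB-GLM fit of the two-group model,
and a Wald test on the group coefficient referred to a moderated-t
distribution. Calls near the significance/fold thresholds may differ from
DESeq2 proper (no Cox-Reid adjustment, no MAP shrinkage of fold changes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .stats import bh_adjust
from scipy import stats as sps

__all__ = [
    "SampleMeta",
    "CountMatrix",
    "TranscriptFragment",
    "AlleleTranscriptModel",
    "compute_cpm",
    "expressed_filter",
    "size_factors",
    "de_test",
    "artifact_gene_filter",
    "ortholog_filter",
    "tf_expression_change",
    "classify_lof",
]

DE_COLUMNS = ["gene_id", "log2fc", "se", "pvalue", "fdr", "direction"]


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    genotype: str
    tissue: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus sample metadata.

    ``counts``: DataFrame indexed by gene_id, columns are sample_ids.
    ``samples``: DataFrame indexed by sample_id with columns genotype,
    tissue, replicate.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.counts.columns) != set(self.samples.index):
            raise ValueError("count columns and sample metadata rows disagree")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        key = self.samples[["genotype", "tissue", "replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate (genotype, tissue, replicate) = {tuple(dup)}"
            )
        # keep metadata ordered like the count columns
        self.samples = self.samples.loc[list(self.counts.columns)]

    def subset(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(sample_ids)].copy(),
            self.samples.loc[list(sample_ids)].copy(),
        )

    def group_samples(self, genotype: str, tissue: str) -> list[str]:
        m = (self.samples["genotype"] == genotype) & (
            self.samples["tissue"] == tissue
        )
        return list(self.samples.index[m])


def compute_cpm(matrix: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million: counts scaled so each sample column sums to 1e6."""
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero library size")
    return counts / totals * 1e6


def expressed_filter(
    cpm: pd.DataFrame,
    samples: pd.DataFrame,
    tissue: str,
    threshold: float = 1.0,
) -> set[str]:
    """Genes with CPM >= threshold in at least one sample of the tissue.

    The CPM table must cover all samples of the tissue (mutant + control);
    the >= boundary is inclusive.
    """
    cols = list(samples.index[samples["tissue"] == tissue])
    if not cols:
        raise ValueError(f"no samples for tissue {tissue!r}")
    sub = cpm[cols]
    return set(sub.index[(sub >= threshold).any(axis=1)])


def size_factors(counts: pd.DataFrame | np.ndarray) -> pd.Series | np.ndarray:
    """Median-of-ratios normalization factors, rescaled to geometric mean 1.

    Reference = per-gene geometric mean over samples, using only genes with
    nonzero counts in every sample (no pseudo-reference fallback).
    """
    arr = counts.to_numpy() if isinstance(counts, pd.DataFrame) else np.asarray(counts)
    ok = (arr > 0).all(axis=1)
    if not ok.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "median-of-ratios needs at least one (pseudo-reference fallback "
            "is disabled)"
        )
    sub = arr[ok].astype(float)
    ref = np.exp(np.log(sub).mean(axis=1))
    f = np.median(sub / ref[:, None], axis=0)
    f = f / np.exp(np.mean(np.log(f)))
    if isinstance(counts, pd.DataFrame):
        return pd.Series(f, index=counts.columns)
    return f


# ---------------------------------------------------------------------------
# NB Wald engine internals


def _moment_dispersion(
    y: np.ndarray, s: np.ndarray, grp: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-gene method-of-moments dispersion pooled across both groups.

    Normalized counts q = y/s; within-group sum of squares around the group
    means divided by the residual dof estimates Var(q); with
    Var(y_j/s_j) ~= mu/s_j + alpha mu^2, alpha = (v - mu mean(1/s)) / mu^2.
    """
    q = y / s[None, :]
    mu = q.mean(axis=1)
    ss = np.zeros(y.shape[0])
    dof = 0
    for g in np.unique(grp):
        qg = q[:, grp == g]
        ss += ((qg - qg.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += qg.shape[1] - 1
    v = ss / dof
    alpha = (v - mu * np.mean(1.0 / s)) / np.maximum(mu, 1e-12) ** 2
    return alpha, mu, dof


def _trend_moderate(
    alpha_raw: np.ndarray,
    mu: np.ndarray,
    dof: int,
    prior_df: float,
) -> np.ndarray:
    """Shrink raw dispersions toward a robust alpha(mu) = a0 + a1/mu trend.

    Weighted average with weights (residual dof, prior_df) — the classic
    moderation that stabilizes per-gene estimates at 3v3 replication without
    which the Wald test is badly anticonservative.
    """
    pos = alpha_raw > 0
    if pos.sum() >= 50:
        X = np.column_stack([np.ones(int(pos.sum())), 1.0 / mu[pos]])
        t = alpha_raw[pos]
        w = np.ones(t.size)
        coef = np.array([np.median(t), 0.0])
        for _ in range(3):
            coef, *_ = np.linalg.lstsq(X * w[:, None], t * w, rcond=None)
            r = np.abs(t - X @ coef)
            w = 1.0 / np.maximum(r, np.median(r) + 1e-12)
        a0, a1 = max(float(coef[0]), 1e-8), max(float(coef[1]), 0.0)
    else:
        a0, a1 = float(np.median(np.maximum(alpha_raw, 1e-8))), 0.0
    trend = a0 + a1 / np.maximum(mu, 1e-12)
    shrunk = (dof * np.maximum(alpha_raw, 0.0) + prior_df * trend) / (
        dof + prior_df
    )
    return np.maximum(shrunk, 1e-8)


def _nb_wald_fit(
    y: np.ndarray,
    s: np.ndarray,
    grp: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 30,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized IRLS fit of log mu_ij = log s_j + b0 + b1 * x_j per gene.

    Returns (b1, se_b1) in natural-log units; weights w = mu/(1 + alpha mu)
    are the NB2 Fisher weights for the log link.
    """
    x = (grp == grp.max()).astype(float) if grp.dtype != float else grp
    offs = np.log(s)[None, :]
    q = y / s[None, :]
    m0 = np.maximum(q[:, x == 0].mean(axis=1), 1e-8)
    m1 = np.maximum(q[:, x == 1].mean(axis=1), 1e-8)
    b0 = np.log(m0)
    b1 = np.log(m1) - np.log(m0)
    Sw = Swx = Swxx = det = np.ones_like(b0)
    for _ in range(max_iter):
        eta = np.clip(offs + b0[:, None] + b1[:, None] * x[None, :], -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offs) + (y - mu) / mu
        Sw = w.sum(axis=1)
        Swx = (w * x).sum(axis=1)
        Swxx = (w * x * x).sum(axis=1)
        Swz = (w * z).sum(axis=1)
        Swxz = (w * x * z).sum(axis=1)
        det = Sw * Swxx - Swx**2
        det = np.where(det <= 0, np.nan, det)
        nb0 = (Swxx * Swz - Swx * Swxz) / det
        nb1 = (Sw * Swxz - Swx * Swz) / det
        nb1 = np.clip(nb1, -20, 20)
        done = np.nanmax(np.abs(nb1 - b1)) < tol
        b0, b1 = nb0, nb1
        if done:
            break
    se = np.sqrt(Sw / det)
    return b1, se


def de_test(
    matrix: CountMatrix,
    mutant: str,
    control: str,
    tissue: str,
    genes: Iterable[str] | None = None,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Per-gene NB Wald test of mutant vs control within one tissue.

    Returns a DataFrame with columns gene_id, log2fc, se, pvalue, fdr,
    direction. ``genes`` restricts testing (typically the expressed-filter
    output); genes with zero counts across both groups are dropped before
    testing and the BH family is the genes actually tested. Direction calls:
    up iff fdr < 0.05 (strict) and log2fc >= 1 (inclusive); down mirrored.
    """
    mcols = matrix.group_samples(mutant, tissue)
    ccols = matrix.group_samples(control, tissue)
    if len(mcols) < 2 or len(ccols) < 2:
        raise ValueError(
            f"need >=2 replicates per group; got {len(mcols)} for {mutant!r} "
            f"and {len(ccols)} for {control!r} in tissue {tissue!r}"
        )
    cols = ccols + mcols
    counts = matrix.counts[cols]
    if genes is not None:
        counts = counts.loc[counts.index.intersection(set(genes))]
    nonzero = counts.sum(axis=1) > 0
    counts = counts[nonzero]
    y = counts.to_numpy(dtype=float)
    grp = np.array([0] * len(ccols) + [1] * len(mcols))
    s = np.asarray(size_factors(counts))
    alpha_raw, mu, dof = _moment_dispersion(y, s, grp)
    alpha = _trend_moderate(alpha_raw, mu, dof, prior_df)
    b1, se = _nb_wald_fit(y, s, grp, alpha)
    log2fc = b1 / np.log(2)
    se2 = se / np.log(2)
    tstat = b1 / se
    pvalue = 2.0 * sps.t.sf(np.abs(tstat), df=dof + prior_df)
    pvalue = np.where(np.isnan(pvalue), 1.0, pvalue)
    fdr = bh_adjust(pvalue)
    direction = np.where(
        (fdr < fdr_threshold) & (log2fc >= lfc_threshold),
        "up",
        np.where(
            (fdr < fdr_threshold) & (log2fc <= -lfc_threshold),
            "down",
            "not_de",
        ),
    )
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2fc": log2fc,
            "se": se2,
            "pvalue": pvalue,
            "fdr": fdr,
            "direction": direction,
        }
    ).reset_index(drop=True)


def artifact_gene_filter(
    de_results_by_allele: Mapping[str, pd.DataFrame],
    qualifying_alleles: Iterable[str],
) -> set[str]:
    """Genes DE in strictly more than half of the qualifying alleles.

    These recur across unrelated mutants (control-line genetic differences,
    not TF regulation) and are removed from every allele's DEG list. The
    qualifying allele set is an explicit input: the study restricted it to
    alleles from tissues where no single TF dominated the mutant read share.
    """
    qualifying = set(qualifying_alleles)
    if not qualifying:
        raise ValueError("qualifying allele set is empty")
    missing = qualifying - set(de_results_by_allele)
    if missing:
        raise ValueError(f"qualifying alleles missing DE results: {sorted(missing)}")
    n = len(qualifying)
    tally: dict[str, int] = {}
    for allele in sorted(qualifying):
        de = de_results_by_allele[allele]
        for g in de.loc[de["direction"] != "not_de", "gene_id"]:
            tally[g] = tally.get(g, 0) + 1
    return {g for g, c in tally.items() if c > n / 2}


def ortholog_filter(
    genes: Iterable[str], mapping: pd.DataFrame
) -> dict[str, str]:
    """Keep genes with a 1-to-1 W22/B73 gene-model mapping.

    ``mapping`` columns: w22_id, b73_id, one_to_one (bool). Returns
    {w22_id: b73_id} for the retained genes, so downstream enrichment can
    work in B73 coordinates (where the GCN/Y1H predictions live).
    """
    one = mapping[mapping["one_to_one"].astype(bool)]
    for col in ("w22_id", "b73_id"):
        if one[col].duplicated().any():
            dup = one.loc[one[col].duplicated(), col].iloc[0]
            raise ValueError(
                f"duplicate one-to-one claim for {col} {dup!r}"
            )
    lut = dict(zip(one["w22_id"], one["b73_id"]))
    return {g: lut[g] for g in genes if g in lut}


class TfExpressionChange(NamedTuple):
    log2fc: float
    se: float
    significant: bool
    status: Literal["tested", "untested"]


def tf_expression_change(de: pd.DataFrame, tf_gene: str) -> TfExpressionChange:
    """The TF's own log2 fold change +/- SE in its mutant allele.

    A TF filtered out before testing (below the expression filter) yields an
    explicit ``untested`` status rather than an exception.
    """
    row = de[de["gene_id"] == tf_gene]
    if row.empty:
        return TfExpressionChange(float("nan"), float("nan"), False, "untested")
    r = row.iloc[0]
    return TfExpressionChange(
        float(r["log2fc"]), float(r["se"]), r["direction"] != "not_de", "tested"
    )


@dataclass(frozen=True)
class TranscriptFragment:
    """One assembled transcript fragment relative to the Mu insertion."""

    side: Literal["five_prime", "three_prime"]
    initial_aug_in_frame: bool
    encoded_protein_fraction: float

    def __post_init__(self) -> None:
        if self.side not in ("five_prime", "three_prime"):
            raise ValueError(f"side must be five_prime/three_prime, got {self.side!r}")
        if not 0.0 <= self.encoded_protein_fraction <= 1.0:
            raise ValueError("encoded_protein_fraction must be in [0, 1]")

    def encodes_functional_product(self) -> bool:
        if self.side == "five_prime":
            return self.initial_aug_in_frame
        return self.encoded_protein_fraction >= 0.5


@dataclass
class AlleleTranscriptModel:
    allele_id: str
    fragments: list[TranscriptFragment]

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("transcript model needs at least one fragment")


def classify_lof(
    model: AlleleTranscriptModel,
) -> Literal["loss_of_function", "not_loss_of_function"]:
    """Loss-of-function call from assembled mutant transcript structure.

    An allele is loss-of-function iff every fragment fails to encode a
    functional product: a 5' fragment fails when its initial AUG is
    out-of-frame; a 3' fragment fails when it would encode strictly less
    than half of the normal protein.
    """
    if any(f.encodes_functional_product() for f in model.fragments):
        return "not_loss_of_function"
    return "loss_of_function"
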