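"""Gene-set statistics for predicted-target validation.

Hypergeometric enrichment of GCN-predicted targets among an allele's DEGs
(with the n1 / n3 network-support thresholds), GO term over-representation,
the representation-factor overlap test between two independent mutant alleles
of the same TF, and the classification of Y1H-predicted targets against the
DE calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

from .stats import HypergeomParams, bh_adjust, hypergeom_tail

__all__ = [
    "PredictionSet",
    "EnrichmentResult",
    "OverlapTest",
    "support_threshold_targets",
    "gcn_target_enrichment",
    "go_enrichment",
    "allele_overlap_test",
    "classify_y1h_targets",
    "direction_split",
]

Direction = Literal["up", "down", "both"]


@dataclass
class PredictionSet:
    """Predicted targets of one TF.

    ``targets``: DataFrame with columns gene_id, source ("Y1H" or "GCN"),
    support (number of co-expression networks predicting the edge; 1 for Y1H).
    """

    tf_id: str
    targets: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.targets.duplicated(subset=["gene_id", "source"])
        if dup.any():
            g = self.targets.loc[dup, "gene_id"].iloc[0]
            raise ValueError(f"duplicate predicted target {g!r} in {self.tf_id}")
        if (self.targets["support"] < 1).any():
            raise ValueError("per-network support must be >= 1")
        bad = set(self.targets["source"]) - {"Y1H", "GCN"}
        if bad:
            raise ValueError(f"unknown prediction source(s): {sorted(bad)}")

    def gcn_targets(self) -> set[str]:
        t = self.targets
        return set(t.loc[t["source"] == "GCN", "gene_id"])

    def y1h_targets(self) -> set[str]:
        t = self.targets
        return set(t.loc[t["source"] == "Y1H", "gene_id"])


@dataclass
class EnrichmentResult:
    params: HypergeomParams
    pvalue: float
    fold_enrichment: float
    direction: Direction

    @property
    def significant(self) -> bool:
        return self.pvalue < 0.05


@dataclass
class OverlapTest:
    """Shared-DEG statistics between two independent alleles of one TF."""

    n_a: int
    n_b: int
    shared: int
    universe: int
    expected: float
    representation_factor: float
    pvalue: float
    possible: int
    proportion: float
    direction: Literal["up", "down"]

    @property
    def significant(self) -> bool:
        return self.representation_factor > 1.0 and self.pvalue < 0.05


def support_threshold_targets(preds: PredictionSet, n_min: int = 1) -> set[str]:
    """GCN targets predicted by at least ``n_min`` networks (n1, n3, ...)."""
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    t = preds.targets
    m = (t["source"] == "GCN") & (t["support"] >= n_min)
    return set(t.loc[m, "gene_id"])


def _fold_enrichment(x: int, m: int, k: int, N: int) -> float:
    # observed / expected where expected = (k/N) * m
    if k * m == 0:
        return float("nan")
    return x * N / (k * m)


def gcn_target_enrichment(
    degs: Iterable[str],
    targets: Iterable[str],
    universe: Iterable[str],
    direction: Direction = "both",
) -> EnrichmentResult:
    """Hypergeometric enrichment of predicted targets among DEGs.

    Roles: N = universe size (expressed, nonredundant predicted targets
    genome-wide), m = expressed predicted targets of this TF, k = DEGs,
    x = DEGs that are predicted targets. DEGs are restricted to the universe
    before counting; fold enrichment = x / ((k/N) * m).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty enrichment universe")
    tgt = set(targets)
    if not tgt:
        raise ValueError("empty predicted-target set")
    if not tgt <= uni:
        raise ValueError("targets must be a subset of the universe")
    deg = set(degs) & uni
    params = HypergeomParams(
        x=len(deg & tgt), m=len(tgt), N=len(uni), k=len(deg)
    )
    return EnrichmentResult(
        params=params,
        pvalue=hypergeom_tail(params),
        fold_enrichment=_fold_enrichment(params.x, params.m, params.k, params.N),
        direction=direction,
    )


def go_enrichment(
    degs: Iterable[str],
    go_table: Mapping[str, set[str]],
    annotated_universe: Iterable[str],
    direction: Direction = "both",
) -> pd.DataFrame:
    """Per-term GO over-representation among DEGs.

    Roles: N = annotated expressed genes, m = genes with the term, k = DEGs
    with any annotation, x = DEGs with the term. Primary significance is the
    unadjusted p < 0.05; a BH-adjusted column (``fdr``) is appended as a
    clearly supplementary aid and plays no role in the p<0.05 call. Terms
    with m = 0 are skipped. Run separately on up- and down-regulated sets.
    """
    uni = set(annotated_universe)
    if not uni:
        raise ValueError("empty annotated universe")
    deg = set(degs) & uni
    rows = []
    for term in sorted(go_table):
        term_genes = set(go_table[term]) & uni
        if not term_genes:
            continue
        params = HypergeomParams(
            x=len(deg & term_genes), m=len(term_genes), N=len(uni), k=len(deg)
        )
        rows.append(
            {
                "term": term,
                "x": params.x,
                "m": params.m,
                "k": params.k,
                "N": params.N,
                "pvalue": hypergeom_tail(params),
                "fold_enrichment": _fold_enrichment(
                    params.x, params.m, params.k, params.N
                ),
                "direction": direction,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term", "x", "m", "k", "N", "pvalue", "fold_enrichment", "direction"],
    )
    if len(out):
        out["significant"] = out["pvalue"] < 0.05
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    else:
        out["significant"] = pd.Series(dtype=bool)
        out["fdr"] = pd.Series(dtype=float)
    return out


def allele_overlap_test(
    degs_a: Iterable[str],
    degs_b: Iterable[str],
    universe: Iterable[str],
    direction: Literal["up", "down"],
) -> OverlapTest:
    """Representation-factor test for shared DEGs between two alleles.

    expected = n_a * n_b / universe; representation factor = shared/expected;
    p = upper-tail hypergeometric of the shared count; possible shared DEGs
    = min(n_a, n_b) within the direction; proportion = shared / possible.
    Significant iff representation factor > 1 AND p < 0.05.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty expressed universe")
    a = set(degs_a) & uni
    b = set(degs_b) & uni
    shared = len(a & b)
    expected = len(a) * len(b) / len(uni)
    if expected == 0 and shared > 0:
        raise ValueError("shared DEGs with zero expectation: inconsistent inputs")
    params = HypergeomParams(x=shared, m=len(a), N=len(uni), k=len(b))
    possible = min(len(a), len(b))
    return OverlapTest(
        n_a=len(a),
        n_b=len(b),
        shared=shared,
        universe=len(uni),
        expected=expected,
        representation_factor=shared / expected if expected > 0 else float("nan"),
        pvalue=hypergeom_tail(params),
        possible=possible,
        proportion=shared / possible if possible > 0 else float("nan"),
        direction=direction,
    )


def classify_y1h_targets(
    targets: Iterable[str],
    de: pd.DataFrame,
    expressed: Iterable[str],
    mapped: Iterable[str],
) -> dict[str, str]:
    """Classify Y1H-predicted targets as up / down / not_de / untested.

    ``untested`` covers targets without a 1-to-1 genome annotation and
    targets not expressed in the assayed tissue; everything else takes its
    DE direction call.
    """
    expressed = set(expressed)
    mapped = set(mapped)
    lut = dict(zip(de["gene_id"], de["direction"]))
    out: dict[str, str] = {}
    for g in sorted(set(targets)):
        if g not in mapped or g not in expressed:
            out[g] = "untested"
        else:
            out[g] = lut.get(g, "untested")
    return out


def direction_split(de: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Partition DE calls into (up, down) gene sets; not_de is excluded."""
    up = set(de.loc[de["direction"] == "up", "gene_id"])
    down = set(de.loc[de["direction"] == "down", "gene_id"])
    return up, down
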