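import itertools

import numpy as np
import pandas as pd
import pytest

from grnval.expression import CountMatrix


def make_count_matrix(counts: np.ndarray, genotypes, tissue="leaf") -> CountMatrix:
    """Small CountMatrix helper: one replicate index per genotype repeat."""
    counts = np.asarray(counts)
    seen: dict[str, int] = {}
    ids, meta = [], []
    for g in genotypes:
        seen[g] = seen.get(g, 0) + 1
        sid = f"{g}_r{seen[g]}"
        ids.append(sid)
        meta.append((sid, g, tissue, seen[g]))
    frame = pd.DataFrame(
        counts,
        index=[f"g{i + 1}" for i in range(counts.shape[0])],
        columns=ids,
    )
    samples = pd.DataFrame(
        meta, columns=["sample_id", "genotype", "tissue", "replicate"]
    ).set_index("sample_id")
    return CountMatrix(frame, samples)


def enumerate_hypergeom_tail(x: int, m: int, N: int, k: int) -> float:
    """Brute-force P(X >= x): count k-subsets of an N-universe with >= x of
    the m marked elements, over all C(N, k) subsets."""
    marked = set(range(m))
    hits = sum(
        1
        for subset in itertools.combinations(range(N), k)
        if len(marked.intersection(subset)) >= x
    )
    from math import comb

    return hits / comb(N, k)


def bh_reference(p):
    """Independent textbook BH step-up: p_(i) * n / i with cumulative min."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * n / np.arange(1, n + 1)
    for i in range(n - 2, -1, -1):
        adj[i] = min(adj[i], adj[i + 1])
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
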