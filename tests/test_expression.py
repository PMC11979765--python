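"""DE engine and expression-side filters: CPM, size factors, NB Wald test,
artifact/ortholog filters, TF self-expression, loss-of-function calls."""

import numpy as np
import pandas as pd
import pytest

from grnval.expression import (
    artifact_gene_filter,
    classify_lof,
    compute_cpm,
    de_test,
    expressed_filter,
    ortholog_filter,
    size_factors,
    tf_expression_change,
)
from grnval.simulate import SimulationConfig, simulate_counts, simulate_transcript_models

from conftest import make_count_matrix


class TestCpm:
    def test_direct_value_and_column_sums(self):
        counts = np.array([[10, 40], [999_990, 160]])
        m = make_count_matrix(counts, ["wt", "mut"])
        cpm = compute_cpm(m)
        assert cpm.iloc[0, 0] == pytest.approx(10.0)
        assert cpm.sum(axis=0).to_numpy() == pytest.approx([1e6, 1e6])

    def test_all_zero_gene_and_scale_invariance(self):
        counts = np.array([[0, 0], [50, 80], [150, 120]])
        m = make_count_matrix(counts, ["wt", "mut"])
        cpm = compute_cpm(m)
        assert (cpm.iloc[0] == 0).all()
        doubled = make_count_matrix(counts * [2, 1], ["wt", "mut"])
        assert np.allclose(compute_cpm(doubled), cpm)

    def test_zero_library_names_sample(self):
        m = make_count_matrix(np.array([[0, 5]]), ["wt", "mut"])
        with pytest.raises(ValueError, match="wt_r1"):
            compute_cpm(m)


class TestExpressedFilter:
    def test_boundaries(self):
        m = make_count_matrix(np.eye(2, dtype=int), ["wt", "mut"])
        cpm = pd.DataFrame(
            {"wt_r1": [0.5, 0.0], "mut_r1": [0.9, 1.0]}, index=["g1", "g2"]
        )
        kept = expressed_filter(cpm, m.samples, "leaf")
        assert kept == {"g2"}  # 1.0 passes (>=), 0.9 does not
        assert expressed_filter(cpm, m.samples, "leaf", threshold=0) == {"g1", "g2"}
        with pytest.raises(ValueError):
            expressed_filter(cpm, m.samples, "root")


class TestSizeFactors:
    def test_identical_and_doubled_samples(self):
        base = np.array([[10, 10], [20, 20], [400, 400]])
        assert size_factors(pd.DataFrame(base)).to_numpy() == pytest.approx([1.0, 1.0])
        doubled = base * [1, 2]
        f = size_factors(pd.DataFrame(doubled)).to_numpy()
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_permutation_equivariance(self, rng):
        counts = pd.DataFrame(rng.poisson(100, size=(50, 4)) + 1)
        f = size_factors(counts).to_numpy()
        perm = [2, 0, 3, 1]
        fp = size_factors(counts.iloc[:, perm]).to_numpy()
        assert fp == pytest.approx(f[perm])

    def test_requires_a_gene_nonzero_everywhere(self):
        counts = pd.DataFrame([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(counts)


def _sim_two_group(rng, n_genes=400, n_true=0, fold=4.0, mean=None, disp=0.1):
    mu = rng.lognormal(np.log(200), 1.0, n_genes) if mean is None else np.full(n_genes, float(mean))
    fc = np.where(np.arange(n_genes) < n_true, fold, 1.0)
    lam_wt = np.tile(mu[:, None], (1, 3))
    lam_mut = np.tile((mu * fc)[:, None], (1, 3))
    lam = np.hstack([lam_wt, lam_mut])
    y = rng.poisson(rng.gamma(1.0 / disp, lam * disp))
    return make_count_matrix(y, ["wt"] * 3 + ["mut"] * 3)


class TestDeTest:
    def test_duplicated_columns_give_zero_log2fc(self):
        base = np.array([[120, 80, 100], [40, 55, 61], [500, 430, 460]])
        counts = np.hstack([base, base])
        m = make_count_matrix(counts, ["wt"] * 3 + ["mut"] * 3)
        de = de_test(m, "mut", "wt", "leaf")
        assert de["log2fc"].to_numpy() == pytest.approx(0.0, abs=1e-8)
        assert (de["direction"] == "not_de").all()

    def test_sign_flips_when_labels_swap(self, rng):
        m = _sim_two_group(rng, n_genes=300, n_true=30)
        fwd = de_test(m, "mut", "wt", "leaf").set_index("gene_id")
        rev = de_test(m, "wt", "mut", "leaf").set_index("gene_id")
        assert fwd["log2fc"].to_numpy() == pytest.approx(
            -rev.loc[fwd.index, "log2fc"].to_numpy(), abs=1e-6
        )

    def test_requires_two_replicates(self):
        m = make_count_matrix(np.array([[5, 5, 5]]), ["wt", "wt", "mut"])
        with pytest.raises(ValueError, match="replicates"):
            de_test(m, "mut", "wt", "leaf")

    def test_null_rejection_near_nominal(self, rng):
        m = _sim_two_group(rng, n_genes=4000, n_true=0)
        de = de_test(m, "mut", "wt", "leaf")
        rate = float((de["pvalue"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_power_on_strong_fold_change(self, rng):
        # 4-fold genes at mean 500, dispersion 0.05, embedded in a null
        # background so size factors are not distorted
        m = _sim_two_group(rng, n_genes=2000, n_true=200, fold=4.0, mean=500, disp=0.05)
        de = de_test(m, "mut", "wt", "leaf").set_index("gene_id")
        true_ids = [f"g{i + 1}" for i in range(200)]
        up_rate = float((de.loc[true_ids, "direction"] == "up").mean())
        assert up_rate >= 0.95


class TestTfExpressionChange:
    def test_untested_and_identical(self):
        de = pd.DataFrame(
            {"gene_id": ["g1"], "log2fc": [0.0], "se": [0.1],
             "pvalue": [1.0], "fdr": [1.0], "direction": ["not_de"]}
        )
        r = tf_expression_change(de, "g1")
        assert (r.log2fc, r.significant, r.status) == (0.0, False, "tested")
        assert tf_expression_change(de, "gX").status == "untested"

    def test_knockdown_recovery(self, rng):
        # TF at 0.25x WT: mean estimated log2fc within +-0.3 of -2
        ests = []
        for _ in range(100):
            m = _sim_two_group(rng, n_genes=300, n_true=0, mean=None, disp=0.05)
            counts = m.counts.copy()
            tf_mu = 200.0
            wt = rng.poisson(rng.gamma(20.0, tf_mu * 0.05, 3))
            mut = rng.poisson(rng.gamma(20.0, tf_mu * 0.25 * 0.05, 3))
            counts.loc["g1"] = np.concatenate([wt, mut])
            m2 = make_count_matrix(counts.to_numpy(), ["wt"] * 3 + ["mut"] * 3)
            de = de_test(m2, "mut", "wt", "leaf")
            ests.append(tf_expression_change(de, "g1").log2fc)
        assert abs(float(np.mean(ests)) - (-2.0)) <= 0.3


class TestArtifactFilter:
    def _de(self, genes_de):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(10)],
             "direction": ["up" if f"g{i}" in genes_de else "not_de" for i in range(10)]}
        )

    def test_strict_majority_rule(self):
        by_allele = {f"a{i}": self._de({"g1"} if i < 3 else set()) for i in range(5)}
        by_allele["a5"] = self._de({"g2"})
        # g1 DE in 3/5 qualifying alleles -> removed; g2 in 1/5 -> kept
        removed = artifact_gene_filter(by_allele, {f"a{i}" for i in range(5)})
        assert removed == {"g1"}
        # 3 of 6 is not strictly more than half
        removed6 = artifact_gene_filter(by_allele, set(by_allele))
        assert removed6 == set()

    def test_order_invariance_and_empty_error(self):
        by_allele = {f"a{i}": self._de({"g1"} if i != 0 else set()) for i in range(3)}
        fwd = artifact_gene_filter(by_allele, list(by_allele))
        rev = artifact_gene_filter(dict(reversed(by_allele.items())),
                                   list(reversed(list(by_allele))))
        assert fwd == rev == {"g1"}
        with pytest.raises(ValueError):
            artifact_gene_filter(by_allele, set())


class TestOrthologFilter:
    def _map(self):
        return pd.DataFrame(
            {"w22_id": ["g1", "g2", "g3"],
             "b73_id": ["b1", "b2", "b3"],
             "one_to_one": [True, False, True]}
        )

    def test_absent_and_non_one_to_one_dropped(self):
        kept = ortholog_filter({"g1", "g2", "g4"}, self._map())
        assert kept == {"g1": "b1"}

    def test_duplicate_claim_rejected(self):
        m = self._map()
        m.loc[1] = ["g1", "b9", True]
        with pytest.raises(ValueError, match="duplicate"):
            ortholog_filter({"g1"}, m)

    def test_identity_mapping_passthrough(self):
        m = pd.DataFrame({"w22_id": ["g1", "g2"], "b73_id": ["g1", "g2"],
                          "one_to_one": [True, True]})
        assert ortholog_filter({"g1", "g2"}, m) == {"g1": "g1", "g2": "g2"}


class TestClassifyLof:
    @pytest.mark.parametrize(
        "model,label",
        simulate_transcript_models(),
        ids=[m.allele_id for m, _ in simulate_transcript_models()],
    )
    def test_labeled_fixture_reproduced(self, model, label):
        assert classify_lof(model) == label
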