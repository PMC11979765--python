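"""LC-MS phenolic pipeline: LOD, AUA, tech-rep averaging, QC filters,
control consistency, dual-control testing, and the compound accounting."""

import numpy as np
import pandas as pd
import pytest

from grnval.metabolomics import (
    MetaboliteTable,
    average_tech_reps,
    compute_lod,
    control_consistency_filter,
    dual_control_test,
    filter_compounds,
    lod_table,
    normalize_aua,
)
from grnval.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_metabolites,
    qc_boundary_fixture,
)


def build_table(values_by_genotype, noise=None, weights=50.0, reps=3):
    """One-batch table: values_by_genotype maps genotype -> per-compound
    log2 level (scalar or array); optional additive per-sample noise."""
    genotypes = list(values_by_genotype)
    compounds = [f"c{i + 1}" for i in
                 range(np.atleast_1d(values_by_genotype[genotypes[0]]).size)]
    cols, meta, data = [], [], {}
    k = 0
    for g in genotypes:
        base = np.atleast_1d(np.asarray(values_by_genotype[g], dtype=float))
        for r in range(1, reps + 1):
            sid = f"{g}_b{r}"
            v = base.copy()
            if noise is not None:
                v = v + noise[k]
                k += 1
            data[sid] = np.power(2.0, v)
            cols.append(sid)
            meta.append((sid, g, 1, False, weights, sid, r))
    for j in (1, 2):
        sid = f"blank_{j}"
        data[sid] = np.full(len(compounds), 4.0)
        cols.append(sid)
        meta.append((sid, "blank", 1, True, np.nan, sid, j))
    areas = pd.DataFrame(data, index=compounds)[cols]
    samples = pd.DataFrame(
        meta, columns=["sample_id", "genotype", "batch", "is_blank",
                       "weight_mg", "tech_rep_group", "bio_rep"]
    ).set_index("sample_id")
    return MetaboliteTable(areas, samples)


class TestLodAndAua:
    @pytest.mark.parametrize("blanks,expected", [
        ([100, 120, 80], 300.0),
        ([50], 150.0),
    ])
    def test_lod_is_three_times_mean_blank(self, blanks, expected):
        assert compute_lod(blanks) == pytest.approx(expected)

    def test_degenerate_and_missing_blanks(self):
        assert compute_lod([0.0, 0.0]) == 0.0
        with pytest.raises(ValueError):
            compute_lod([])

    def test_aua_and_tech_rep_averaging(self):
        assert normalize_aua(500.0, 50.0) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            normalize_aua(500.0, 0.0)
        t = build_table({"m": [10.0]})
        # add a diverging tech rep for m_b1
        areas = t.areas.copy()
        areas["m_b1_t2"] = areas["m_b1"] * 1.2
        samples = t.samples.copy()
        samples.loc["m_b1_t2"] = ["m", 1, False, 50.0, "m_b1", 1]
        t2 = MetaboliteTable(areas, samples)
        bio, meta = average_tech_reps(t2)
        assert bio.loc["c1", "m_b1"] == pytest.approx(
            (t.areas.loc["c1", "m_b1"] * 1.1) / 50.0
        )
        assert meta.loc["m_b1", "n_tech"] == 2
        # singleton groups pass through unchanged
        assert bio.loc["c1", "m_b2"] == pytest.approx(
            t.areas.loc["c1", "m_b2"] / 50.0
        )

    def test_aua_scale_equivariance(self, rng):
        t = build_table({"m": [10.0, 12.0], "w": [10.0, 11.0]},
                        noise=rng.normal(0, 0.2, (6, 2)))
        bio1, meta = average_tech_reps(t)
        doubled = MetaboliteTable(t.areas * 2.0, t.samples.copy())
        bio2, _ = average_tech_reps(doubled)
        assert np.allclose(bio2, bio1 * 2.0)
        r1 = dual_control_test(t, "m", ("w", "w"))
        r2 = dual_control_test(doubled, "m", ("w", "w"))
        assert r1["pvalue_a"].to_numpy() == pytest.approx(r2["pvalue_a"].to_numpy())


class TestQcBoundaries:
    def test_strict_inequality_fixture(self):
        table, expected = qc_boundary_fixture()
        qc = filter_compounds(table).set_index("compound")
        for rec in expected.itertuples():
            assert qc.loc[rec.compound, "status"] == rec.status, rec.compound

    def test_below_lod_uses_own_batch(self):
        # batch 2 has 10x higher blanks; a value clearing batch-1 LOD but
        # not batch-2 LOD must count below-LOD only in batch 2
        cols = ["a_b1", "a_b2", "blank1", "blank2"]
        areas = pd.DataFrame({"a_b1": [100.0], "a_b2": [100.0],
                              "blank1": [10.0], "blank2": [100.0]},
                             index=["c1"])
        samples = pd.DataFrame(
            {"sample_id": cols, "genotype": ["m", "m", "blank", "blank"],
             "batch": [1, 2, 1, 2], "is_blank": [False, False, True, True],
             "weight_mg": [50.0, 50.0, np.nan, np.nan],
             "tech_rep_group": cols, "bio_rep": [1, 2, 1, 1]}
        ).set_index("sample_id")
        t = MetaboliteTable(areas, samples)
        qc = filter_compounds(t)
        assert qc["frac_below_lod"].iloc[0] == pytest.approx(0.5)


class TestControlConsistency:
    def test_power_and_single_compound_bh(self, rng):
        noise = rng.normal(0, 0.05, 6)
        t = build_table({"ca": [10.0], "cb": [12.0]}, noise=noise)
        removed, res = control_consistency_filter(t, "ca", "cb")
        assert removed == {"c1"}
        assert res["fdr"].iloc[0] == pytest.approx(res["pvalue"].iloc[0])

    def test_null_removal_rate_below_nominal(self, rng):
        hits = 0
        n = 150
        for _ in range(n):
            noise = rng.normal(0, 0.3, 6)
            t = build_table({"ca": [10.0], "cb": [10.0]}, noise=noise)
            removed, _ = control_consistency_filter(t, "ca", "cb")
            hits += bool(removed)
        assert hits / n < 0.09

    def test_missing_control_group_rejected(self):
        t = build_table({"ca": [10.0]})
        with pytest.raises(ValueError):
            control_consistency_filter(t, "ca", "cb")


class TestDualControl:
    def test_identical_groups_not_significant(self, rng):
        noise = rng.normal(0, 0.2, 9)
        t = build_table({"m": [10.0], "ca": [10.0], "cb": [10.0]}, noise=noise)
        out = dual_control_test(t, "m", ("ca", "cb"))
        assert not out["significant"].any()

    def test_quarter_fold_recovered(self, rng):
        noise = rng.normal(0, 0.05, 9 * 3)
        t = build_table({"m": [8.0, 10.0, 9.0], "ca": [10.0, 10.0, 9.0],
                         "cb": [10.0, 10.0, 9.0]}, noise=noise.reshape(9, 3))
        out = dual_control_test(t, "m", ("ca", "cb")).set_index("compound")
        assert bool(out.loc["c1", "significant"])
        assert out.loc["c1", "log2fc_a"] == pytest.approx(-2.0, abs=0.5)
        assert out.loc["c1", "log2fc_b"] == pytest.approx(-2.0, abs=0.5)
        assert not out.loc["c2", "significant"]

    def test_single_control_significance_is_insufficient(self, rng):
        noise = rng.normal(0, 0.05, 9)
        # mutant differs from control a only: not significant overall
        t = build_table({"m": [12.0], "ca": [10.0], "cb": [12.0]}, noise=noise)
        out = dual_control_test(t, "m", ("ca", "cb"))
        assert (out["fdr_a"] < 0.05).all()
        assert not out["significant"].any()

    def test_dual_significance_subset_of_single(self, rng):
        cfg = SimulationConfig(seed=5, n_tfs=1)
        _, truth = simulate_counts(cfg)
        t = simulate_metabolites(cfg, truth)
        mutant = sorted(truth.alleles)[0]
        out = dual_control_test(t, mutant, ("W22_rg", "W22_UM"))
        sig = set(out.loc[out["significant"], "compound"])
        sig_a = set(out.loc[out["fdr_a"] < 0.05, "compound"])
        sig_b = set(out.loc[out["fdr_b"] < 0.05, "compound"])
        assert sig <= sig_a and sig <= sig_b


class TestCompoundAccounting:
    def test_31_to_28_to_24(self):
        """The designed 31-compound study: 3 fail QC, 4 differ between
        controls, 24 analyzable; low measurement noise makes every removal
        decision power-1."""
        cfg = SimulationConfig(seed=3, met_noise_sd=0.1)
        _, truth = simulate_counts(cfg)
        table = simulate_metabolites(cfg, truth)
        qc = filter_compounds(table)
        kept = list(qc.loc[qc["status"] == "kept", "compound"])
        assert len(qc) == 31 and len(kept) == 28
        tr = truth.metabolite_truth.set_index("compound")
        assert set(qc.loc[qc["status"] == "removed_lod", "compound"]) == set(
            tr.index[tr["designed_status"] == "fail_lod"]
        )
        assert set(qc.loc[qc["status"] == "removed_missing", "compound"]) == set(
            tr.index[tr["designed_status"] == "fail_missing"]
        )
        removed, _ = control_consistency_filter(table, "W22_rg", "W22_UM",
                                                compounds=kept)
        assert removed == set(tr.index[tr["designed_status"] == "control_diff"])
        analyzable = [c for c in kept if c not in removed]
        assert len(analyzable) == 24
        # the designed mutant effects are exactly the significant set
        for allele in sorted(truth.alleles):
            out = dual_control_test(table, allele, ("W22_rg", "W22_UM"),
                                    compounds=analyzable)
            sig = set(out.loc[out["significant"], "compound"])
            designed = set(tr.index[(tr["designed_status"] == "mutant_effect")
                                    & (tr["effect_allele"] == allele)])
            assert sig == designed
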