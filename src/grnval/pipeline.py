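"""Stage drivers: simulate -> de -> enrich -> scan -> metab -> traits -> report.

Each stage reads the plain-text inputs under ``<outdir>/inputs``, writes its
tables under ``<outdir>``, logs the gene counts entering and leaving every
filter (the primary debugging surface for filter-order questions), and
appends itself to a machine-readable run manifest carrying the config hash,
seed and package version. Rerunning with the same seed and config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as gio
from .enrichment import (
    PredictionSet,
    allele_overlap_test,
    classify_y1h_targets,
    direction_split,
    gcn_target_enrichment,
    go_enrichment,
    support_threshold_targets,
)
from .expression import (
    artifact_gene_filter,
    compute_cpm,
    de_test,
    expressed_filter,
    ortholog_filter,
    tf_expression_change,
)
from .io import PipelineConfig
from .metabolomics import (
    control_consistency_filter,
    dual_control_test,
    filter_compounds,
    lod_table,
)
from .motifs import consensus_to_pwm, intersect_hits, scan_sequence, score_distribution
from .simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_counts,
    simulate_metabolites,
    simulate_predictions,
    simulate_promoters,
    simulate_traits,
    simulate_transcript_models,
)
from .stats import bh_adjust, compare_trait_to_control, flowering_time_flag

logger = logging.getLogger(__name__)

STAGES = ("simulate", "de", "enrich", "scan", "metab", "traits", "report")


def _inputs(outdir: str | Path) -> Path:
    return Path(outdir) / "inputs"


def _update_manifest(outdir: Path, stage: str, files: list[str],
                     config: PipelineConfig, extra: dict | None = None) -> None:
    path = outdir / "run_manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": {},
    }
    manifest["stages"][stage] = {"outputs": sorted(files), **(extra or {})}
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------


def stage_simulate(outdir: str | Path, sim: SimulationConfig,
                   config: PipelineConfig) -> GroundTruth:
    """Generate every pipeline input with planted ground truth."""
    outdir = Path(outdir)
    ind = _inputs(outdir)
    ind.mkdir(parents=True, exist_ok=True)

    matrix, truth = simulate_counts(sim)
    gio.write_counts(matrix, ind / "counts.tsv", ind / "samples.tsv")

    predictions, ortho, go = simulate_predictions(sim, truth)
    pred_rows = pd.concat(
        [p.targets.assign(tf_id=tf) for tf, p in predictions.items()],
        ignore_index=True,
    )[["tf_id", "gene_id", "source", "support"]]
    gio.write_predictions(pred_rows, ind / "predictions.tsv")
    gio.write_orthologs(ortho, ind / "orthologs.tsv")
    gio.write_go(go, ind / "go.tsv")

    seqs, regions, _ = simulate_promoters(sim, truth)
    gio.write_fasta(seqs, ind / "promoters.fasta")
    gio.write_bed(regions, ind / "cloned_regions.bed")

    met = simulate_metabolites(sim, truth)
    gio.write_metabolites(met, ind / "metabolite_areas.tsv",
                          ind / "metabolite_samples.tsv")

    heights, flowering = simulate_traits(sim, truth)
    heights.to_csv(ind / "heights.tsv", sep="\t", index=False)
    flowering.to_csv(ind / "flowering.tsv", sep="\t", index=False)

    models = simulate_transcript_models(sim)
    rows = [
        {"allele_id": m.allele_id, "fragment": i, "side": f.side,
         "initial_aug_in_frame": f.initial_aug_in_frame,
         "encoded_protein_fraction": f.encoded_protein_fraction, "label": label}
        for m, label in models
        for i, f in enumerate(m.fragments)
    ]
    pd.DataFrame(rows).to_csv(ind / "transcript_models.tsv", sep="\t", index=False)

    design = pd.DataFrame(
        [
            {"allele": a, "tf_id": tf, "tf_gene": truth.tf_genes[tf],
             "tissue": sim.tissue, "control": sim.control_genotype}
            for a, tf in sorted(truth.alleles.items())
        ]
    )
    design.to_csv(ind / "alleles.tsv", sep="\t", index=False)

    (ind / "truth.json").write_text(json.dumps({
        "tf_genes": truth.tf_genes,
        "alleles": truth.alleles,
        "true_targets": {tf: dict(sorted(d.items()))
                         for tf, d in truth.true_targets.items()},
        "background_degs": {a: dict(sorted(d.items()))
                            for a, d in truth.background_degs.items()},
        "artifact_genes": sorted(truth.artifact_genes),
        "unmapped_genes": sorted(truth.unmapped_genes),
        "planted_sites": truth.planted_sites,
        "metabolite_truth": truth.metabolite_truth.to_dict("records"),
        "trait_truth": truth.trait_truth,
    }, indent=2, sort_keys=True) + "\n")

    _update_manifest(outdir, "simulate",
                     [str(p.relative_to(outdir)) for p in ind.iterdir()], config,
                     {"sim_config": dataclasses.asdict(sim)})
    return truth


def stage_de(outdir: str | Path, config: PipelineConfig) -> pd.DataFrame:
    """Per-allele DE calls with the expressed / artifact / ortholog filters."""
    outdir = Path(outdir)
    ind = _inputs(outdir)
    matrix = gio.read_counts(ind / "counts.tsv", ind / "samples.tsv")
    design = pd.read_csv(ind / "alleles.tsv", sep="\t")
    ortho = gio.read_orthologs(ind / "orthologs.tsv")
    cpm = compute_cpm(matrix)

    de_by_allele: dict[str, pd.DataFrame] = {}
    expressed_by_allele: dict[str, set[str]] = {}
    files = []
    for rec in design.itertuples():
        expressed = expressed_filter(cpm, matrix.samples, rec.tissue,
                                     threshold=config.cpm_min)
        logger.info("%s: %d genes pass CPM >= %s in %s",
                    rec.allele, len(expressed), config.cpm_min, rec.tissue)
        de = de_test(matrix, rec.allele, rec.control, rec.tissue,
                     genes=expressed, fdr_threshold=config.fdr,
                     lfc_threshold=config.min_log2fc)
        de_by_allele[rec.allele] = de
        expressed_by_allele[rec.allele] = expressed
        f = outdir / f"de_{rec.allele}.tsv"
        de.to_csv(f, sep="\t", index=False)
        files.append(f.name)

    artifacts = artifact_gene_filter(de_by_allele, set(de_by_allele))
    logger.info("artifact filter: %d genes DE in more than half of %d alleles",
                len(artifacts), len(de_by_allele))
    pd.DataFrame({"gene_id": sorted(artifacts)}).to_csv(
        outdir / "artifact_genes.tsv", sep="\t", index=False)
    files.append("artifact_genes.tsv")

    summary_rows = []
    for rec in design.itertuples():
        de = de_by_allele[rec.allele]
        degs = de[de["direction"] != "not_de"]
        n0 = len(degs)
        degs = degs[~degs["gene_id"].isin(artifacts)]
        n1 = len(degs)
        mapped = ortholog_filter(degs["gene_id"], ortho)
        degs = degs[degs["gene_id"].isin(mapped)].copy()
        degs["b73_id"] = degs["gene_id"].map(mapped)
        logger.info("%s: DEGs %d -> %d (artifact) -> %d (1-to-1 ortholog)",
                    rec.allele, n0, n1, len(degs))
        f = outdir / f"degs_{rec.allele}.tsv"
        degs[["gene_id", "b73_id", "log2fc", "se", "pvalue", "fdr",
              "direction"]].to_csv(f, sep="\t", index=False)
        files.append(f.name)
        tf_row = tf_expression_change(de, rec.tf_gene)
        summary_rows.append({
            "allele": rec.allele, "tf_id": rec.tf_id, "tissue": rec.tissue,
            "n_expressed": len(expressed_by_allele[rec.allele]),
            "n_degs_raw": n0, "n_degs_post_artifact": n1,
            "n_degs_final": len(degs),
            "n_up": int((degs["direction"] == "up").sum()),
            "n_down": int((degs["direction"] == "down").sum()),
            "tf_log2fc": tf_row.log2fc, "tf_se": tf_row.se,
            "tf_significant": tf_row.significant, "tf_status": tf_row.status,
        })
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "de_summary.tsv", sep="\t", index=False)
    files.append("de_summary.tsv")
    _update_manifest(outdir, "de", files, config)
    return summary


def _load_filtered_degs(outdir: Path, allele: str) -> pd.DataFrame:
    return pd.read_csv(outdir / f"degs_{allele}.tsv", sep="\t")


def stage_enrich(outdir: str | Path, config: PipelineConfig) -> dict:
    """GCN n1/n3 + GO enrichment, allele overlap, Y1H classification."""
    outdir = Path(outdir)
    ind = _inputs(outdir)
    design = pd.read_csv(ind / "alleles.tsv", sep="\t")
    preds = gio.read_predictions(ind / "predictions.tsv")
    ortho = gio.read_orthologs(ind / "orthologs.tsv")
    go = gio.read_go(ind / "go.tsv")
    matrix = gio.read_counts(ind / "counts.tsv", ind / "samples.tsv")
    cpm = compute_cpm(matrix)

    pred_sets = {
        tf: PredictionSet(tf_id=tf, targets=g[["gene_id", "source", "support"]]
                          .reset_index(drop=True))
        for tf, g in preds.groupby("tf_id")
    }

    expressed_by_tissue = {
        t: expressed_filter(cpm, matrix.samples, t, threshold=config.cpm_min)
        for t in design["tissue"].unique()
    }
    mapped_all = set(ortholog_filter(ortho["w22_id"], ortho))

    enr_rows, overlap_rows, go_frames, y1h_rows = [], [], [], []
    for tf, tf_design in design.groupby("tf_id", sort=True):
        tissue = tf_design["tissue"].iloc[0]
        expressed = expressed_by_tissue[tissue]
        # GCN universe: union of every TF's predicted targets, restricted to
        # expressed 1-to-1 genes (narrowest reading of "nonredundant")
        union_targets = set(preds.loc[preds["source"] == "GCN", "gene_id"])
        universe = union_targets & expressed & mapped_all
        n1 = support_threshold_targets(pred_sets[tf], 1) & universe
        n3 = support_threshold_targets(pred_sets[tf], config.n3_support) & universe
        annotated = set().union(*go.values()) & expressed & mapped_all

        degs_by_allele = {}
        for allele in tf_design["allele"]:
            degs = _load_filtered_degs(outdir, allele)
            up, down = direction_split(degs)
            degs_by_allele[allele] = (up, down)
            for label, tset in (("n1", n1), ("n3", n3)):
                for direction, dset in (("up", up), ("down", down),
                                        ("both", up | down)):
                    if not tset:
                        continue
                    r = gcn_target_enrichment(dset, tset, universe, direction)
                    enr_rows.append({
                        "tf_id": tf, "allele": allele, "prediction_set": label,
                        "direction": direction, "x": r.params.x, "m": r.params.m,
                        "k": r.params.k, "N": r.params.N, "pvalue": r.pvalue,
                        "fold_enrichment": r.fold_enrichment,
                        "significant": r.significant,
                    })
            for direction, dset in (("up", up), ("down", down)):
                gt = go_enrichment(dset, go, annotated, direction)
                gt.insert(0, "allele", allele)
                gt.insert(0, "tf_id", tf)
                go_frames.append(gt)
            y1h = pred_sets[tf].y1h_targets()
            full_de = pd.read_csv(outdir / f"de_{allele}.tsv", sep="\t")
            cls = classify_y1h_targets(y1h, full_de, expressed, mapped_all)
            for g, status in cls.items():
                y1h_rows.append({"tf_id": tf, "allele": allele,
                                 "gene_id": g, "status": status})
        alleles = list(tf_design["allele"])
        shared_universe = expressed & mapped_all
        for i in range(len(alleles)):
            for j in range(i + 1, len(alleles)):
                for d_i, direction in ((0, "up"), (1, "down")):
                    ov = allele_overlap_test(
                        degs_by_allele[alleles[i]][d_i],
                        degs_by_allele[alleles[j]][d_i],
                        shared_universe, direction)
                    overlap_rows.append({
                        "tf_id": tf, "allele_a": alleles[i],
                        "allele_b": alleles[j], "direction": direction,
                        "n_a": ov.n_a, "n_b": ov.n_b, "shared": ov.shared,
                        "universe": ov.universe, "expected": ov.expected,
                        "representation_factor": ov.representation_factor,
                        "pvalue": ov.pvalue, "possible": ov.possible,
                        "proportion": ov.proportion,
                        "significant": ov.significant,
                    })

    enr = pd.DataFrame(enr_rows)
    enr.to_csv(outdir / "gcn_enrichment.tsv", sep="\t", index=False)
    pd.concat(go_frames, ignore_index=True).to_csv(
        outdir / "go_enrichment.tsv", sep="\t", index=False)
    ov = pd.DataFrame(overlap_rows)
    ov.to_csv(outdir / "allele_overlap.tsv", sep="\t", index=False)
    y1h = pd.DataFrame(y1h_rows)
    y1h.to_csv(outdir / "y1h_classification.tsv", sep="\t", index=False)
    files = ["gcn_enrichment.tsv", "go_enrichment.tsv", "allele_overlap.tsv",
             "y1h_classification.tsv"]
    _update_manifest(outdir, "enrich", files, config)
    return {"enrichment": enr, "overlap": ov, "y1h": y1h}


def stage_scan(outdir: str | Path, config: PipelineConfig) -> pd.DataFrame:
    """Scan promoters for the consensus TFBS; subset to cloned regions."""
    outdir = Path(outdir)
    ind = _inputs(outdir)
    seqs = gio.read_fasta(ind / "promoters.fasta")
    regions = gio.read_bed(ind / "cloned_regions.bed")
    model = consensus_to_pwm(config.consensus, config.gc_content)
    dist = score_distribution(model)
    hits = []
    for sid in sorted(seqs):
        hits.extend(scan_sequence(model, seqs[sid], sequence_id=sid,
                                  p_threshold=config.motif_p, dist=dist))
    within = intersect_hits(hits, regions)
    frame = pd.DataFrame(
        [{"sequence_id": h.sequence_id, "start": h.start, "end": h.end,
          "strand": h.strand, "score": round(h.score, 4),
          "pvalue": h.pvalue} for h in within]
    )
    frame.to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
    gio.write_bed(
        [(h.sequence_id, h.start, h.end, model.name,
          round(-np.log10(max(h.pvalue, 1e-300)), 3), h.strand)
         for h in within],
        outdir / "motif_hits.bed",
    )
    logger.info("motif scan: %d hits, %d within cloned regions",
                len(hits), len(within))
    _update_manifest(outdir, "scan", ["motif_hits.tsv", "motif_hits.bed"], config)
    return frame


def stage_metab(outdir: str | Path, config: PipelineConfig,
                controls: tuple[str, str] = ("W22_rg", "W22_UM")) -> dict:
    """Metabolite QC, control-consistency removal, dual-control tests."""
    outdir = Path(outdir)
    ind = _inputs(outdir)
    table = gio.read_metabolites(ind / "metabolite_areas.tsv",
                                 ind / "metabolite_samples.tsv")
    lods = lod_table(table)
    qc = filter_compounds(table, lods=lods, lod_frac=config.lod_frac,
                          missing_frac=config.missing_frac)
    kept = list(qc.loc[qc["status"] == "kept", "compound"])
    logger.info("metabolite QC: %d/%d compounds kept", len(kept), len(qc))
    removed_ctrl, ctrl_tests = control_consistency_filter(
        table, controls[0], controls[1], compounds=kept,
        fdr_threshold=config.fdr)
    analyzable = [c for c in kept if c not in removed_ctrl]
    logger.info("control consistency: %d removed, %d analyzable",
                len(removed_ctrl), len(analyzable))
    mutants = sorted(
        set(table.samples.loc[~table.samples["is_blank"], "genotype"])
        - set(controls)
    )
    tests = pd.concat(
        [dual_control_test(table, m, controls, compounds=analyzable,
                           fdr_threshold=config.fdr) for m in mutants],
        ignore_index=True,
    )
    qc["removed_control_diff"] = qc["compound"].isin(removed_ctrl)
    qc.to_csv(outdir / "metabolite_qc.tsv", sep="\t", index=False)
    ctrl_tests.to_csv(outdir / "metabolite_control_tests.tsv", sep="\t", index=False)
    tests.to_csv(outdir / "metabolite_tests.tsv", sep="\t", index=False)
    files = ["metabolite_qc.tsv", "metabolite_control_tests.tsv",
             "metabolite_tests.tsv"]
    _update_manifest(outdir, "metab", files, config,
                     {"n_compounds": len(qc), "n_kept_qc": len(kept),
                      "n_analyzable": len(analyzable)})
    return {"qc": qc, "control_tests": ctrl_tests, "tests": tests,
            "analyzable": analyzable}


def stage_traits(outdir: str | Path, config: PipelineConfig,
                 control: str = "W22") -> dict:
    """Per-field trait t-tests (BH within field) and flowering flags."""
    outdir = Path(outdir)
    ind = _inputs(outdir)
    heights = pd.read_csv(ind / "heights.tsv", sep="\t")
    flowering = pd.read_csv(ind / "flowering.tsv", sep="\t")
    rows = []
    for fld, fh in heights.groupby("field"):
        ctrl = fh[fh["genotype"] == control]
        for trait in ("plant_height_cm", "ear_height_cm"):
            sub = []
            for genotype, gh in fh[fh["genotype"] != control].groupby("genotype"):
                res = compare_trait_to_control(gh[trait], ctrl[trait])
                sub.append({"field": fld, "genotype": genotype, "trait": trait,
                            "effect_log2": res.effect, "statistic": res.statistic,
                            "pvalue": res.pvalue})
            subdf = pd.DataFrame(sub)
            subdf["fdr"] = bh_adjust(subdf["pvalue"].to_numpy())
            subdf["significant"] = subdf["fdr"] < config.fdr
            rows.append(subdf)
    tests = pd.concat(rows, ignore_index=True)
    frows = []
    for fld, ff in flowering.groupby("field"):
        ctrl_mean = {
            t: ff.loc[ff["genotype"] == control, t].mean()
            for t in ("tassel_days", "silk_days")
        }
        for rec in ff[ff["genotype"] != control].itertuples():
            for t in ("tassel_days", "silk_days"):
                frows.append({
                    "field": fld, "genotype": rec.genotype, "trait": t,
                    "mutant_days": getattr(rec, t),
                    "control_mean_days": round(ctrl_mean[t], 3),
                    "flag": flowering_time_flag(getattr(rec, t), ctrl_mean[t],
                                                max_days=config.flowering_days),
                })
    flags = pd.DataFrame(frows)
    tests.to_csv(outdir / "trait_tests.tsv", sep="\t", index=False)
    flags.to_csv(outdir / "flowering_flags.tsv", sep="\t", index=False)
    _update_manifest(outdir, "traits", ["trait_tests.tsv", "flowering_flags.tsv"],
                     config)
    return {"tests": tests, "flags": flags}


def stage_report(outdir: str | Path, config: PipelineConfig) -> pd.DataFrame:
    """Join stage outputs into one per-allele summary table."""
    outdir = Path(outdir)
    summary = pd.read_csv(outdir / "de_summary.tsv", sep="\t")
    enr = pd.read_csv(outdir / "gcn_enrichment.tsv", sep="\t")
    ov = pd.read_csv(outdir / "allele_overlap.tsv", sep="\t")
    y1h = pd.read_csv(outdir / "y1h_classification.tsv", sep="\t")
    met = pd.read_csv(outdir / "metabolite_tests.tsv", sep="\t")

    both = enr[enr["direction"] == "both"]
    piv = both.pivot_table(index="allele", columns="prediction_set",
                           values=["pvalue", "fold_enrichment"], aggfunc="first")
    piv.columns = [f"{a}_{b}" for a, b in piv.columns]
    report = summary.merge(piv.reset_index(), on="allele", how="left")

    ov_long = pd.concat([
        ov[["allele_a", "significant"]].rename(columns={"allele_a": "allele"}),
        ov[["allele_b", "significant"]].rename(columns={"allele_b": "allele"}),
    ])
    ov_sig = ov_long.groupby("allele")["significant"].any().rename(
        "overlap_significant")
    report = report.merge(ov_sig.reset_index(), on="allele", how="left")

    y1h_counts = (y1h.groupby(["allele", "status"]).size().unstack(fill_value=0)
                  .add_prefix("y1h_"))
    report = report.merge(y1h_counts.reset_index(), on="allele", how="left")

    met_sig = (met[met["significant"]].groupby("mutant").size()
               .rename("n_metabolites_significant"))
    report = report.merge(met_sig.reset_index().rename(
        columns={"mutant": "allele"}), on="allele", how="left")
    report["n_metabolites_significant"] = (
        report["n_metabolites_significant"].fillna(0).astype(int))
    report.to_csv(outdir / "report.tsv", sep="\t", index=False)
    _update_manifest(outdir, "report", ["report.tsv"], config)
    return report


def run_all(outdir: str | Path, sim: SimulationConfig | None = None,
            config: PipelineConfig | None = None) -> pd.DataFrame:
    """Run every stage in order; returns the final report table."""
    config = config or PipelineConfig()
    sim = sim or SimulationConfig(seed=config.seed)
    stage_simulate(outdir, sim, config)
    stage_de(outdir, config)
    stage_enrich(outdir, config)
    stage_scan(outdir, config)
    stage_metab(outdir, config)
    stage_traits(outdir, config)
    return stage_report(outdir, config)
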