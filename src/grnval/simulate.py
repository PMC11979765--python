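"""Synthetic study generator with planted ground truth.

Emulates, at desk scale, the structure of a reverse-genetics GRN validation
study: NB-distributed RNA-seq counts for wild-type vs mutant-allele replicate
groups with a designed subset of predicted targets truly perturbed; GCN/Y1H
prediction tables with per-network support (the n1/n3 structure over 45
networks); 1-to-1 ortholog and GO annotation tables; promoter sequences with
planted degenerate motif instances and cloned-region BED intervals; mutant
transcript-fragment models with known loss-of-function status; and a
two-batch LC-MS peak-area table with blanks, designed below-LOD and missing
compounds, control-line differences and mutant effects.

Determinism: every sub-generator draws from its own PCG64 stream derived
from the master seed via a fixed spawn key, so outputs are bit-identical
under a fixed seed and adding a new generator never perturbs the others.

The metabolite generator is replicate-matched by default: replicate noise
and sample weights are realized once per compound / replicate index and
shared across genotypes, so group contrasts equal their designed effects
exactly and the QC accounting is deterministic. Set ``iid_noise=True`` for
fully independent sampling in calibration studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import AlleleTranscriptModel, CountMatrix, TranscriptFragment
from .enrichment import PredictionSet
from .metabolomics import MetaboliteTable
from .motifs import consensus_to_pwm, reverse_complement, BASES

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_counts",
    "simulate_predictions",
    "simulate_promoters",
    "simulate_metabolites",
    "simulate_transcript_models",
    "simulate_traits",
    "qc_boundary_fixture",
]

_STREAMS = {
    "counts": 1,
    "predictions": 2,
    "promoters": 3,
    "metabolites": 4,
    "traits": 5,
    "transcripts": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults mirror the study design
    at desk scale (5,000 genes, 2 TFs x 2 alleles, 3 replicates, 400
    predicted targets over 45 networks, 31 compounds in 2 LC-MS batches)."""

    seed: int = 1
    # expression
    n_genes: int = 5000
    n_tfs: int = 2
    alleles_per_tf: int = 2
    reps_per_group: int = 3
    tissue: str = "seedling_leaf"
    control_genotype: str = "W22"
    mean_log_mu: float = float(np.log(200.0))
    sd_log_mu: float = 1.0
    nb_dispersion: float = 0.1
    fold_change: float = 4.0
    tf_self_fold: float = 0.25
    size_factor_low: float = 0.7
    size_factor_high: float = 1.4
    n_background_degs: int = 100
    n_artifact_genes: int = 40
    artifact_fold: float = 2.0
    # predictions
    targets_per_tf: int = 400
    true_target_fraction: float = 0.25
    n_networks: int = 45
    support_frac_n3: float = 0.5
    y1h_targets_per_tf: int = 30
    frac_unmapped: float = 0.05
    n_go_terms: int = 40
    # promoters
    gc_content: float = 0.47
    n_promoters: int = 100
    promoter_length: int = 1000
    frac_planted: float = 0.5
    consensus: str = "NGAANNTTCN"
    cloned_margin: int = 25
    # metabolites
    n_compounds: int = 31
    n_fail_lod: int = 2
    n_fail_missing: int = 1
    n_control_diff: int = 4
    n_mutant_effect: int = 2
    mutant_effect_log2: float = -2.0
    control_diff_log2: float = 2.0
    met_noise_sd: float = 0.3
    met_mean_log2_low: float = 14.0
    met_mean_log2_high: float = 20.0
    blank_log2: float = 10.0
    n_blanks_per_batch: int = 3
    tech_rep_frac: float = 0.2
    missing_target_frac: float = 0.15
    iid_noise: bool = False
    # traits
    n_trait_mutants: int = 12
    n_control_rows: int = 11
    plants_per_row: int = 10
    n_fields: int = 2
    height_mean_cm: float = 200.0
    height_cv: float = 0.07
    ear_frac: float = 0.55
    ear_cv: float = 0.10
    flowering_mean_days: float = 67.0
    flowering_sd_days: float = 1.0
    flowering_effect_days: float = 7.0
    height_effect_factor: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_target_fraction <= 1.0:
            raise ValueError("true_target_fraction must be in [0, 1]")
        if self.targets_per_tf > self.n_genes:
            raise ValueError("targets_per_tf exceeds n_genes")
        for name in ("n_genes", "n_tfs", "reps_per_group", "n_compounds",
                     "promoter_length", "n_promoters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.promoter_length < len(self.consensus):
            raise ValueError("promoter_length shorter than the motif")

    @property
    def gene_ids(self) -> list[str]:
        return [f"W22G{i:05d}" for i in range(1, self.n_genes + 1)]

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i + 1}" for i in range(self.n_tfs)]

    def alleles_of(self, tf: str) -> list[str]:
        return [f"{tf.lower()}-m{j + 1}" for j in range(self.alleles_per_tf)]


@dataclass
class GroundTruth:
    """Planted truth: what a perfect pipeline should recover."""

    tf_genes: dict[str, str] = field(default_factory=dict)
    alleles: dict[str, str] = field(default_factory=dict)  # allele -> TF
    true_targets: dict[str, dict[str, int]] = field(default_factory=dict)  # tf -> {gene: sign}
    background_degs: dict[str, dict[str, int]] = field(default_factory=dict)  # allele -> {gene: sign}
    artifact_genes: set[str] = field(default_factory=set)
    unmapped_genes: set[str] = field(default_factory=set)
    planted_sites: list[tuple[str, int, str]] = field(default_factory=list)
    lof_labels: dict[str, bool] = field(default_factory=dict)
    metabolite_truth: pd.DataFrame | None = None
    trait_truth: dict[str, dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# counts


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """NB count matrix for WT + every mutant allele, with planted targets.

    Per-gene baseline means are log-normal; each allele of a TF perturbs the
    TF's true targets by ``fold_change`` (half up, half down), knocks the TF
    gene itself down to ``tf_self_fold``, perturbs ``n_background_degs``
    allele-specific off-target genes, and shares a small set of artifact
    genes perturbed in every mutant (control-line differences). Counts are
    gamma-Poisson with per-sample size factors drawn log-uniform.
    """
    rng = _rng(config.seed, "counts")
    genes = np.array(config.gene_ids)
    truth = GroundTruth()

    mu = rng.lognormal(config.mean_log_mu, config.sd_log_mu, config.n_genes)

    # a fold change of 1 is the null configuration: nothing is truly perturbed
    null_fc = config.fold_change == 1.0
    n_true = 0 if null_fc else int(
        round(config.targets_per_tf * config.true_target_fraction)
    )
    pool = rng.permutation(config.n_genes)
    cursor = 0

    for tf in config.tf_ids:
        tf_gene = str(genes[pool[cursor]])
        cursor += 1
        truth.tf_genes[tf] = tf_gene
        tgt_idx = pool[cursor : cursor + n_true]
        cursor += n_true
        signs = {str(genes[g]): (1 if i < (n_true + 1) // 2 else -1)
                 for i, g in enumerate(tgt_idx)}
        truth.true_targets[tf] = signs
        for allele in config.alleles_of(tf):
            truth.alleles[allele] = tf

    art_idx = pool[cursor : cursor + config.n_artifact_genes]
    cursor += config.n_artifact_genes
    truth.artifact_genes = {str(g) for g in genes[art_idx]}

    for allele in truth.alleles:
        n_bg = 0 if null_fc else config.n_background_degs
        bg_idx = pool[cursor : cursor + n_bg]
        cursor += n_bg
        bg_signs = rng.choice([1, -1], size=len(bg_idx))
        truth.background_degs[allele] = {
            str(genes[g]): int(s) for g, s in zip(bg_idx, bg_signs)
        }

    gene_pos = {g: i for i, g in enumerate(genes)}
    groups: list[tuple[str, np.ndarray]] = []
    wt_mean = mu.copy()
    groups.append((config.control_genotype, wt_mean))
    for allele, tf in truth.alleles.items():
        m = mu.copy()
        for g, s in truth.true_targets[tf].items():
            m[gene_pos[g]] *= config.fold_change if s > 0 else 1.0 / config.fold_change
        for g, s in truth.background_degs[allele].items():
            m[gene_pos[g]] *= config.fold_change if s > 0 else 1.0 / config.fold_change
        for g in truth.artifact_genes:
            m[gene_pos[g]] *= config.artifact_fold
        m[gene_pos[truth.tf_genes[tf]]] = mu[gene_pos[truth.tf_genes[tf]]] * config.tf_self_fold
        groups.append((allele, m))

    cols, data, meta = [], [], []
    shape = 1.0 / config.nb_dispersion
    for genotype, m in groups:
        for rep in range(1, config.reps_per_group + 1):
            sf = np.exp(
                rng.uniform(np.log(config.size_factor_low),
                            np.log(config.size_factor_high))
            )
            lam = m * sf
            y = rng.poisson(rng.gamma(shape, lam / shape))
            sid = f"{genotype}_{config.tissue}_r{rep}"
            cols.append(sid)
            data.append(y)
            meta.append((sid, genotype, config.tissue, rep))
    counts = pd.DataFrame(
        np.column_stack(data), index=genes, columns=cols
    )
    counts.index.name = "gene_id"
    samples = pd.DataFrame(
        meta, columns=["sample_id", "genotype", "tissue", "replicate"]
    ).set_index("sample_id")
    return CountMatrix(counts, samples), truth


# ---------------------------------------------------------------------------
# predictions, orthologs, GO


def simulate_predictions(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[dict[str, PredictionSet], pd.DataFrame, dict[str, set[str]]]:
    """Prediction tables, the 1-to-1 ortholog map, and a GO annotation table.

    Each TF's GCN prediction set is its true targets (all of them — the
    planted recall) topped up with uniform decoys to ``targets_per_tf``;
    per-edge network support is drawn so ``support_frac_n3`` of edges reach
    support >= 3 (the n3 subset). Y1H targets are an independent draw mixing
    true targets and decoys. Returns (predictions, ortholog_map, go_table).
    """
    rng = _rng(config.seed, "predictions")
    genes = np.array(config.gene_ids)
    predictions: dict[str, PredictionSet] = {}
    for tf in config.tf_ids:
        true = sorted(truth.true_targets.get(tf, {}))
        n_decoys = config.targets_per_tf - len(true)
        if n_decoys < 0:
            raise ValueError("targets_per_tf smaller than the planted true set")
        non_targets = np.setdiff1d(genes, np.array(true + [truth.tf_genes.get(tf, "")]))
        decoys = rng.choice(non_targets, size=n_decoys, replace=False)
        gcn = np.concatenate([np.array(true, dtype=object), decoys])
        is_n3 = rng.random(len(gcn)) < config.support_frac_n3
        support = np.where(
            is_n3,
            rng.integers(3, min(9, config.n_networks + 1), size=len(gcn)),
            rng.integers(1, 3, size=len(gcn)),
        )
        n_y1h_true = min(len(true), config.y1h_targets_per_tf // 2)
        y1h_true = rng.choice(np.array(true, dtype=object), size=n_y1h_true,
                              replace=False) if n_y1h_true else np.array([], dtype=object)
        y1h_decoys = rng.choice(
            non_targets, size=config.y1h_targets_per_tf - n_y1h_true, replace=False
        )
        y1h = np.concatenate([y1h_true, y1h_decoys])
        frame = pd.concat(
            [
                pd.DataFrame({"gene_id": gcn, "source": "GCN", "support": support}),
                pd.DataFrame({"gene_id": y1h, "source": "Y1H", "support": 1}),
            ],
            ignore_index=True,
        )
        predictions[tf] = PredictionSet(tf_id=tf, targets=frame)

    n_unmapped = int(round(config.frac_unmapped * config.n_genes))
    unmapped = {str(g) for g in rng.choice(genes, size=n_unmapped, replace=False)}
    truth.unmapped_genes = unmapped
    ortho = pd.DataFrame(
        {
            "w22_id": genes,
            "b73_id": [g.replace("W22G", "B73G") for g in genes],
            "one_to_one": [g not in unmapped for g in genes],
        }
    )

    go: dict[str, set[str]] = {}
    for t in range(config.n_go_terms):
        size = int(np.exp(rng.uniform(np.log(5), np.log(200))))
        go[f"GO:{t + 1:07d}"] = set(rng.choice(genes, size=size, replace=False))
    return predictions, ortho, go


# ---------------------------------------------------------------------------
# promoters


def simulate_promoters(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[dict[str, str], list[tuple[str, int, int]], list[tuple[str, int, str]]]:
    """Background promoters with planted degenerate motif instances.

    Background bases are i.i.d. at the configured GC content; a random
    subset of promoters receives one planted consensus instance (fixed
    positions take the consensus base, N positions are background draws) at
    a recorded position and strand inside the cloned region. Returns
    (sequences, cloned regions, planted sites); sites are also recorded on
    ``truth.planted_sites``.
    """
    rng = _rng(config.seed, "promoters")
    model = consensus_to_pwm(config.consensus, config.gc_content)
    L = len(model)
    probs = np.array(
        [(1 - config.gc_content) / 2, config.gc_content / 2,
         config.gc_content / 2, (1 - config.gc_content) / 2]
    )
    seqs: dict[str, str] = {}
    regions: list[tuple[str, int, int]] = []
    planted: list[tuple[str, int, str]] = []
    n_planted = int(round(config.frac_planted * config.n_promoters))
    which = set(rng.choice(config.n_promoters, size=n_planted, replace=False))
    base_arr = np.array(list(BASES))
    for p in range(config.n_promoters):
        sid = f"prom{p + 1:03d}"
        seq = "".join(rng.choice(base_arr, size=config.promoter_length, p=probs))
        start_r = config.cloned_margin
        end_r = config.promoter_length - config.cloned_margin
        regions.append((sid, start_r, end_r))
        if p in which:
            word = []
            for i, ch in enumerate(config.consensus.upper()):
                if ch == "N":
                    word.append(str(rng.choice(base_arr, p=probs)))
                else:
                    word.append(ch)
            word_s = "".join(word)
            pos = int(rng.integers(start_r, end_r - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            ins = word_s if strand == "+" else reverse_complement(word_s)
            seq = seq[:pos] + ins + seq[pos + L:]
            planted.append((sid, pos, strand))
        seqs[sid] = seq
    truth.planted_sites = planted
    return seqs, regions, planted


# ---------------------------------------------------------------------------
# metabolites


def simulate_metabolites(
    config: SimulationConfig, truth: GroundTruth
) -> MetaboliteTable:
    """Two-batch LC-MS peak-area table with blanks and designed effects.

    Designed compounds: ``n_fail_lod`` sit at blank level (below the 3x-blank
    LOD in essentially every sample), ``n_fail_missing`` lose
    ``missing_target_frac`` of their values, ``n_control_diff`` differ
    between the two control lines (the shift rides on the UniformMu-derived
    background, i.e. on the color-converted control and every mutant), and
    ``n_mutant_effect`` carry a designed per-allele effect. 20% of batch-1
    samples are duplicated as technical replicates. Replicate-matched by
    default (see module docstring); truth lands on
    ``truth.metabolite_truth``.
    """
    rng = _rng(config.seed, "metabolites")
    c = config
    compounds = [f"cmpd{i + 1:02d}" for i in range(c.n_compounds)]
    controls = ["W22_rg", "W22_UM"]
    mutants = sorted(truth.alleles) if truth.alleles else ["tf1-m1"]
    genotypes = controls + mutants
    reps = range(1, c.reps_per_group + 1)

    n_special = c.n_fail_lod + c.n_fail_missing + c.n_control_diff + c.n_mutant_effect
    if n_special > c.n_compounds:
        raise ValueError("designed compound classes exceed n_compounds")
    order = rng.permutation(c.n_compounds)
    i = 0
    fail_lod = set(order[i : i + c.n_fail_lod]); i += c.n_fail_lod
    fail_missing = set(order[i : i + c.n_fail_missing]); i += c.n_fail_missing
    control_diff = set(order[i : i + c.n_control_diff]); i += c.n_control_diff
    mutant_eff = list(order[i : i + c.n_mutant_effect]); i += c.n_mutant_effect
    eff_allele = {ci: mutants[j % len(mutants)] for j, ci in enumerate(mutant_eff)}

    base = rng.uniform(c.met_mean_log2_low, c.met_mean_log2_high, c.n_compounds)
    base[list(fail_lod)] = c.blank_log2 - 1.0
    if mutant_eff:
        # keep designed-effect compounds comfortably above the LOD even
        # after the (negative) mutant effect
        base[mutant_eff] = rng.uniform(17.0, c.met_mean_log2_high, len(mutant_eff))
    rep_noise = rng.normal(0.0, c.met_noise_sd, size=(c.n_compounds, c.reps_per_group))
    weights = np.clip(rng.normal(50.0, 2.0, size=c.reps_per_group), 40.0, 60.0)

    cols: list[str] = []
    meta_rows: list[tuple] = []
    values: dict[str, np.ndarray] = {}

    half = max(1, len(genotypes) // 2)
    batch_of = {g: (1 if j < half else 2) for j, g in enumerate(genotypes)}

    for g in genotypes:
        for r_i, r in enumerate(reps):
            if c.iid_noise:
                noise = rng.normal(0.0, c.met_noise_sd, c.n_compounds)
                w = float(np.clip(rng.normal(50.0, 2.0), 40.0, 60.0))
            else:
                noise = rep_noise[:, r_i]
                w = float(weights[r_i])
            log2v = base + noise
            for ci in control_diff:
                if g != "W22_rg":  # UniformMu-derived background
                    log2v = log2v.copy()
                    log2v[ci] += c.control_diff_log2
            for ci, allele in eff_allele.items():
                if g == allele:
                    log2v = log2v.copy()
                    log2v[ci] += c.mutant_effect_log2
            area = np.power(2.0, log2v) * (w / 50.0)
            sid = f"{g}_b{r}"
            cols.append(sid)
            values[sid] = area
            meta_rows.append((sid, g, batch_of[g], False, w, f"{g}_b{r}", r))

    # technical replicates: duplicate a fixed fraction of batch-1 samples
    b1 = [s for s in cols if meta_rows[cols.index(s)][2] == 1]
    n_tech = int(np.ceil(c.tech_rep_frac * len(b1)))
    for sid in b1[:n_tech]:
        row = meta_rows[cols.index(sid)]
        tid = sid + "_t2"
        cols.append(tid)
        values[tid] = values[sid].copy()
        meta_rows.append((tid, row[1], row[2], False, row[4], row[5], row[6]))

    # blanks per batch
    for b in (1, 2):
        for j in range(c.n_blanks_per_batch):
            sid = f"blank_b{b}_{j + 1}"
            area = np.power(2.0, c.blank_log2 + rng.normal(0, 0.1, c.n_compounds))
            cols.append(sid)
            values[sid] = area
            meta_rows.append((sid, "blank", b, True, np.nan, sid, j + 1))

    areas = pd.DataFrame(values, index=compounds)[cols]
    areas.index.name = "compound"

    # designed missingness over non-blank samples
    nonblank = [m[0] for m in meta_rows if not m[3]]
    n_missing = int(np.ceil(c.missing_target_frac * len(nonblank)))
    for ci in fail_missing:
        miss = rng.choice(nonblank, size=n_missing, replace=False)
        areas.loc[compounds[ci], miss] = np.nan

    samples = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "genotype", "batch", "is_blank", "weight_mg",
                 "tech_rep_group", "bio_rep"],
    ).set_index("sample_id")

    status = np.array(["null"] * c.n_compounds, dtype=object)
    status[list(fail_lod)] = "fail_lod"
    status[list(fail_missing)] = "fail_missing"
    status[list(control_diff)] = "control_diff"
    status[mutant_eff] = "mutant_effect"
    truth.metabolite_truth = pd.DataFrame(
        {
            "compound": compounds,
            "designed_status": status,
            "effect_allele": [eff_allele.get(i, "") for i in range(c.n_compounds)],
            "effect_log2": [
                c.mutant_effect_log2 if i in eff_allele else 0.0
                for i in range(c.n_compounds)
            ],
        }
    )
    return MetaboliteTable(areas, samples)


# ---------------------------------------------------------------------------
# transcript models


def simulate_transcript_models(
    config: SimulationConfig | None = None,
) -> list[tuple[AlleleTranscriptModel, str]]:
    """Labeled transcript-fragment fixtures spanning every rule branch.

    Covers 5' fragments with the initial AUG in/out of frame, 3' fragments
    at protein fractions 0.49 / 0.50 / 0.51 (the strict "< half" boundary),
    and multi-fragment combinations where a single rescuing fragment flips
    the call. Deterministic; the labels are the ground truth.
    """
    F = TranscriptFragment
    lof, ok = "loss_of_function", "not_loss_of_function"
    cases: list[tuple[list[TranscriptFragment], str]] = [
        ([F("five_prime", False, 0.2)], lof),
        ([F("five_prime", True, 0.3)], ok),
        ([F("five_prime", False, 0.0)], lof),
        ([F("three_prime", False, 0.49)], lof),
        ([F("three_prime", False, 0.50)], ok),
        ([F("three_prime", False, 0.51)], ok),
        ([F("three_prime", True, 0.0)], lof),
        ([F("three_prime", False, 1.0)], ok),
        ([F("three_prime", False, 0.25)], lof),
        ([F("five_prime", True, 1.0)], ok),
        ([F("five_prime", False, 0.1), F("three_prime", False, 0.3)], lof),
        ([F("five_prime", False, 0.1), F("three_prime", False, 0.5)], ok),
        ([F("five_prime", True, 0.1), F("three_prime", False, 0.3)], ok),
        ([F("five_prime", False, 0.2), F("three_prime", False, 0.49)], lof),
        ([F("five_prime", False, 0.2), F("three_prime", False, 0.51)], ok),
        ([F("five_prime", False, 0.3), F("five_prime", False, 0.4)], lof),
        ([F("five_prime", False, 0.3), F("five_prime", True, 0.4)], ok),
        ([F("three_prime", False, 0.1), F("three_prime", False, 0.2)], lof),
        ([F("three_prime", False, 0.1), F("three_prime", False, 0.9)], ok),
        ([F("five_prime", False, 0.0), F("three_prime", False, 0.0)], lof),
        ([F("five_prime", False, 0.49), F("three_prime", False, 0.49)], lof),
        ([F("five_prime", True, 0.49), F("three_prime", False, 0.49)], ok),
    ]
    return [
        (AlleleTranscriptModel(allele_id=f"case{i + 1:02d}", fragments=frags), label)
        for i, (frags, label) in enumerate(cases)
    ]


# ---------------------------------------------------------------------------
# traits


def simulate_traits(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Field-trait tables: plant/ear height per plant, flowering per row.

    Two field environments; one mutant row per allele and 11 control rows
    per field; up to 10 plants per row. One designed mutant with reduced
    height in both fields and one with a +7 day tassel-shedding delay.
    Returns (heights, flowering) long tables.
    """
    rng = _rng(config.seed, "traits")
    c = config
    mutants = [f"mut{i + 1:02d}" for i in range(c.n_trait_mutants)]
    height_mut = mutants[0]
    flower_mut = mutants[1] if len(mutants) > 1 else mutants[0]
    hrows, frows = [], []
    for fld in range(1, c.n_fields + 1):
        rows = [("W22", r + 1) for r in range(c.n_control_rows)] + [
            (m, 1) for m in mutants
        ]
        for genotype, row_i in rows:
            n_pl = int(rng.integers(max(4, c.plants_per_row - 3), c.plants_per_row + 1))
            factor = c.height_effect_factor if genotype == height_mut else 1.0
            ph = rng.normal(c.height_mean_cm * factor,
                            c.height_mean_cm * c.height_cv, n_pl)
            eh = rng.normal(c.height_mean_cm * c.ear_frac * factor,
                            c.height_mean_cm * c.ear_frac * c.ear_cv, n_pl)
            for p in range(n_pl):
                hrows.append(
                    (fld, genotype, row_i, p + 1,
                     round(max(ph[p], 1.0), 1), round(max(eh[p], 1.0), 1))
                )
            shift = c.flowering_effect_days if genotype == flower_mut else 0.0
            tass = c.flowering_mean_days + shift + rng.normal(0, c.flowering_sd_days)
            silk = tass + 2.0 + rng.normal(0, c.flowering_sd_days)
            frows.append((fld, genotype, row_i, round(tass, 1), round(silk, 1)))
    heights = pd.DataFrame(
        hrows, columns=["field", "genotype", "row", "plant",
                        "plant_height_cm", "ear_height_cm"]
    )
    flowering = pd.DataFrame(
        frows, columns=["field", "genotype", "row", "tassel_days", "silk_days"]
    )
    if truth is not None:
        truth.trait_truth = {
            "height_effect_mutant": {"genotype": height_mut,
                                     "factor": c.height_effect_factor},
            "flowering_effect_mutant": {"genotype": flower_mut,
                                        "delay_days": c.flowering_effect_days},
        }
    return heights, flowering


# ---------------------------------------------------------------------------
# deterministic QC boundary fixture


def qc_boundary_fixture(n_samples: int = 100) -> tuple[MetaboliteTable, pd.DataFrame]:
    """Metabolite fixture with compounds engineered at the QC boundaries.

    Six compounds sit at exactly 19 / 20 / 21 % of samples below LOD and
    9 / 10 / 11 % of samples missing (over ``n_samples`` non-blank samples,
    one batch of blanks per batch label kept trivial). The strict ">"
    rules must keep the 19/20% and 9/10% compounds and remove the 21/11%
    ones. Returns (table, expected_status frame).
    """
    if n_samples % 100:
        raise ValueError("n_samples must be a multiple of 100 for exact percents")
    comps = ["lod19", "lod20", "lod21", "miss09", "miss10", "miss11"]
    expected = pd.DataFrame(
        {
            "compound": comps,
            "status": ["kept", "kept", "removed_lod",
                       "kept", "kept", "removed_missing"],
        }
    )
    cols = [f"s{i + 1:03d}" for i in range(n_samples)]
    blank_cols = ["blank_b1", "blank_b2"]
    high, low = 1000.0, 10.0  # LOD = 3 * mean(blank=20) = 60; low < 60 < high
    blank_level = 20.0
    data = {}
    for comp in comps:
        v = np.full(n_samples, high)
        if comp.startswith("lod"):
            n_below = int(comp[3:]) * n_samples // 100
            v[:n_below] = low
        else:
            n_miss = int(comp[4:]) * n_samples // 100
            v[:n_miss] = np.nan
        data[comp] = v
    areas = pd.DataFrame(data, index=cols).T
    areas[blank_cols[0]] = blank_level
    areas[blank_cols[1]] = blank_level
    areas.index.name = "compound"
    meta = pd.DataFrame(
        {
            "sample_id": cols + blank_cols,
            "genotype": ["geno"] * n_samples + ["blank", "blank"],
            "batch": [1 if i < n_samples // 2 else 2 for i in range(n_samples)] + [1, 2],
            "is_blank": [False] * n_samples + [True, True],
            "weight_mg": [50.0] * n_samples + [np.nan, np.nan],
            "tech_rep_group": cols + blank_cols,
            "bio_rep": list(range(1, n_samples + 1)) + [1, 1],
        }
    ).set_index("sample_id")
    return MetaboliteTable(areas, meta), expected
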