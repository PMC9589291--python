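"""End-to-end orchestration: simulate -> label -> k-mers -> models ->
minimal sets -> TFBM matching -> clustering -> enrichment.

Each stage writes plain-text artifacts under the output directory and the
run manifest records the config snapshot, per-stage seeds, row counts,
output digests and every open design decision actually used, so a rerun
with the same manifest reproduces the outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrich, kmers, labeling, models, selection, similarity
from .cluster import cluster_summary, distance_matrix, to_newick, upgma_cut
from .genes import write_go_tsv, write_region_fasta
from .pwm import write_family_map, write_meme
from .simulate import (
    PlantedMotif,
    SimulationConfig,
    generate_dataset,
    write_de_table,
    write_truth_ledger,
)

log = logging.getLogger("coldcre")


@dataclass
class PipelineConfig:
    """All tunables of the analysis; defaults follow the study conditions."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    directions: tuple[str, ...] = ("up",)
    up_fc: float = 1.0
    down_fc: float = -1.0
    alpha: float = 0.05
    null_fc: float = 0.5
    train_fraction: float = 0.8
    n_bins: int = 5
    folds: int = 5
    k_range: tuple[int, ...] = kmers.DEFAULT_K_RANGE
    grid: models.HyperparameterGrid = field(default_factory=models.HyperparameterGrid)
    balance_method: str = "smote"
    selection_rule: str = "derivative"
    selection_eps: float = 1e-4
    selection_fraction: float = 0.90
    cluster_cutoff: float = 0.39
    background_scope: str = "within_family"
    test_sidedness: str = "one-sided"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        motifs = [
            PlantedMotif(**m) if isinstance(m, dict) else m
            for m in sim_raw.pop("planted_motifs", [])
        ]
        for m in motifs:
            m.target_time_points = tuple(m.target_time_points)
        sim = SimulationConfig(planted_motifs=motifs, **_tupled(sim_raw))
        grid_raw = raw.pop("grid", None)
        grid = models.HyperparameterGrid(**_tupled(grid_raw)) if grid_raw else models.HyperparameterGrid()
        return cls(simulation=sim, grid=grid, **_tupled(raw))


def _tupled(d: dict | None) -> dict:
    out = {}
    for k, v in (d or {}).items():
        out[k] = tuple(v) if isinstance(v, list) else v
    return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class RunManifest:
    def __init__(self, config: PipelineConfig, outdir: Path):
        self.data = {
            "config": _config_snapshot(config),
            "seeds": {},
            "digests": {},
            "row_counts": {},
            "wall_time_s": {},
            "decisions": {
                "selection_fraction": config.selection_fraction,
                "selection_rule": config.selection_rule,
                "background_scope": config.background_scope,
                "test_sidedness": config.test_sidedness,
                "balance_scope": "fold",
            },
            "stage_order": [],
            "test_set_access": [],
        }
        self.outdir = outdir

    def stage(self, name: str, seed: int | None = None):
        self.data["stage_order"].append(name)
        if seed is not None:
            self.data["seeds"][name] = seed

    def record_file(self, stage: str, path: Path, rows: int | None = None):
        self.data["digests"][str(path.relative_to(self.outdir))] = _digest(path)
        if rows is not None:
            self.data["row_counts"][f"{stage}:{path.name}"] = rows

    def note_test_access(self, stage: str):
        self.data["test_set_access"].append(stage)

    def save(self):
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(self.data, fh, indent=2, default=str)


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = asdict(config)
    snap["simulation"]["planted_motifs"] = [
        {"motif": m.motif if isinstance(m.motif, str) else m.motif.consensus(),
         "target_time_points": list(m.target_time_points),
         "p_signal": m.p_signal, "p_background": m.p_background}
        for m in config.simulation.planted_motifs
    ]
    return snap


@dataclass
class TimePointModel:
    """Everything the per-time-point modelling loop produces."""

    time: str
    enriched_kmers: list[str]
    report: models.ModelReport
    ramp: selection.PerformanceRamp
    mm_fit: selection.MMFit
    n_minimal: int
    selection_flagged: bool
    minimal_set: list[str]
    enrichment_tables: pd.DataFrame | None = None


def analyze_models(
    genes,
    de: pd.DataFrame,
    config: PipelineConfig,
    index: kmers.PresenceIndex | None = None,
    keep_tables: bool = False,
) -> tuple[dict[str, labeling.ResponseLabelSet], dict[str, TimePointModel]]:
    """Label genes and run the per-time-point modelling chain in memory.

    Returns the labels (with train/test splits filled) and, for each time
    point with at least one five-bin-enriched k-mer, the fitted model,
    ramp, Michaelis-Menten fit and minimal pCRE set.
    """
    tps = config.simulation.time_points
    direction = config.directions[0]
    labels = labeling.label_genes(
        de, up_fc=config.up_fc, down_fc=config.down_fc, alpha=config.alpha,
        null_fc=config.null_fc, time_points=tps,
    )
    if index is None:
        index = kmers.PresenceIndex(genes, k_range=config.k_range)
    out: dict[str, TimePointModel] = {}
    for j, tp in enumerate(tps):
        lab = labeling.split_train_test(
            labels[tp], direction=direction, fraction=config.train_fraction,
            seed=config.seed + 101 * j,
        )
        train_pos = sorted(lab.train_ids["positive"])
        train_neg = sorted(lab.train_ids["negative"])
        res = kmers.binned_enrichment(
            index, train_pos, train_neg, n_bins=config.n_bins,
            alpha=config.alpha, seed=config.seed, return_tables=keep_tables,
        )
        enriched, tables = res if keep_tables else (res, None)
        if not enriched:
            log.warning("no k-mers enriched in all bins at %s hr", tp)
            continue
        mat = kmers.build_matrix(index, enriched, train_pos, train_neg)
        best_hp, diag = models.grid_search_cv(
            mat.values, mat.class_labels, grid=config.grid, folds=config.folds,
            seed=config.seed, balance_method=config.balance_method,
        )
        best_folds = max(diag["results"], key=lambda r: r["mean_f1"])["fold_f1"]
        test_pos = sorted(lab.test_ids["positive"])
        test_neg = sorted(lab.test_ids["negative"])
        test_mat = kmers.build_matrix(index, enriched, test_pos, test_neg)
        rep = models.train_final_and_test(
            mat.values, mat.class_labels, test_mat.values,
            test_mat.class_labels, best_hp, seed=config.seed,
            feature_names=enriched, time=tp, direction=direction,
            cv_f1_folds=best_folds, balance_method=config.balance_method,
        )
        ranked = selection.rank_features(enriched, rep.importances)
        ramp = selection.performance_ramp(
            mat.values, mat.class_labels, ranked, enriched, best_hp,
            full_model_f1=rep.cv_f1, folds=config.folds, seed=config.seed,
            balance_method=config.balance_method,
        )
        fit = selection.fit_mm(ramp)
        n_min, flagged = selection.minimal_feature_count(
            ramp, fit, rule=config.selection_rule, eps=config.selection_eps,
            fraction=config.selection_fraction,
        )
        out[tp] = TimePointModel(
            time=tp, enriched_kmers=enriched, report=rep, ramp=ramp,
            mm_fit=fit, n_minimal=n_min, selection_flagged=flagged,
            minimal_set=ranked[:n_min], enrichment_tables=tables,
        )
        log.info("model %s hr: CV F1 %.3f, test F1 %.3f, minimal %d/%d",
                 tp, rep.cv_f1, rep.test_f1, n_min, len(enriched))
    return labels, out


def run_all(config: PipelineConfig, outdir) -> Path:
    """Run every stage on a simulated dataset; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config, outdir)
    t0 = _time.time()

    # --- simulate -----------------------------------------------------
    manifest.stage("simulate", config.simulation.seed)
    genes, de, library, truth = generate_dataset(config.simulation)
    write_region_fasta(genes, outdir / "genes.fasta")
    write_de_table(de, outdir / "de_table.tsv")
    write_go_tsv(genes, outdir / "go_annotations.tsv")
    write_meme(library, outdir / "tfbm_library.meme")
    write_family_map(library, outdir / "tfbm_families.tsv")
    write_truth_ledger(truth, outdir / "truth_ledger.tsv")
    for f in ("genes.fasta", "de_table.tsv", "go_annotations.tsv",
              "tfbm_library.meme", "tfbm_families.tsv", "truth_ledger.tsv"):
        manifest.record_file("simulate", outdir / f)
    manifest.data["row_counts"]["simulate:genes"] = len(genes)
    manifest.data["row_counts"]["simulate:de_rows"] = len(de)
    log.info("simulate: %d genes, %d DE rows, %d planted instances",
             len(genes), len(de), len(truth))
    manifest.data["wall_time_s"]["simulate"] = round(_time.time() - t0, 2)

    # --- label + models + minimal sets --------------------------------
    t0 = _time.time()
    manifest.stage("label", config.seed)
    manifest.stage("models", config.seed)
    tps = config.simulation.time_points
    index = kmers.PresenceIndex(genes, k_range=config.k_range)
    labels, tpmodels = analyze_models(genes, de, config, index=index,
                                      keep_tables=True)
    manifest.note_test_access("final_evaluation")
    profiles = labeling.encode_profiles(de, tps, up_fc=config.up_fc,
                                        down_fc=config.down_fc, alpha=config.alpha)
    pd.DataFrame(sorted(profiles.items()), columns=["gene_id", "profile"]).to_csv(
        outdir / "profiles.tsv", sep="\t", index=False)
    manifest.record_file("label", outdir / "profiles.tsv", rows=len(profiles))
    for tp in tps:
        lab = labels[tp]
        rows = ([(g, "up") for g in sorted(lab.up_genes)]
                + [(g, "down") for g in sorted(lab.down_genes)]
                + [(g, "negative") for g in sorted(lab.negatives)])
        pd.DataFrame(rows, columns=["gene_id", "label"]).to_csv(
            outdir / f"labels_{tp}.tsv", sep="\t", index=False)
        manifest.record_file("label", outdir / f"labels_{tp}.tsv", rows=len(rows))
        log.info("label %s hr: %d up, %d down, %d negatives", tp,
                 len(lab.up_genes), len(lab.down_genes), len(lab.negatives))
    reports: dict[str, models.ModelReport] = {}
    minimal_sets: dict[str, list[str]] = {}
    for tp, tpm in tpmodels.items():
        reports[tp] = tpm.report
        minimal_sets[tp] = tpm.minimal_set
        if tpm.enrichment_tables is not None:
            tpm.enrichment_tables.to_csv(
                outdir / f"kmer_enrichment_{tp}.tsv", sep="\t", index=False,
                float_format="%.4g")
            manifest.record_file("kmers", outdir / f"kmer_enrichment_{tp}.tsv",
                                 rows=len(tpm.enrichment_tables))
        tpm.report.importance_frame().to_csv(
            outdir / f"importances_{tp}.tsv", sep="\t", index=False,
            float_format="%.6g")
        manifest.record_file("train", outdir / f"importances_{tp}.tsv",
                             rows=len(tpm.enriched_kmers))
        pd.DataFrame(tpm.ramp.points, columns=["n_features", "cv_f1"]).to_csv(
            outdir / f"ramp_{tp}.tsv", sep="\t", index=False)
        with open(outdir / f"mm_fit_{tp}.json", "w") as fh:
            json.dump({"f1_max": tpm.mm_fit.f1_max, "k_half": tpm.mm_fit.k_half,
                       "rss": tpm.mm_fit.rss, "converged": tpm.mm_fit.converged,
                       "n_minimal": tpm.n_minimal,
                       "rule_flagged": tpm.selection_flagged}, fh, indent=2)
        manifest.record_file("select", outdir / f"ramp_{tp}.tsv")
        manifest.record_file("select", outdir / f"mm_fit_{tp}.json")
    manifest.data["wall_time_s"]["models"] = round(_time.time() - t0, 2)

    if len(minimal_sets) < 2:
        log.warning("fewer than two time-point models; stopping after models")
        _write_reports(reports, outdir, manifest)
        manifest.save()
        return outdir

    # --- categorize + pCRE tables -------------------------------------
    pcre_sets = selection.build_pcre_sets(minimal_sets, reports,
                                          direction=config.directions[0])
    all_pcres = sorted({k for s in minimal_sets.values() for k in s})
    categories = selection.categorize(minimal_sets)
    for tp, ps in pcre_sets.items():
        pd.DataFrame(
            {"kmer": ps.kmers,
             "rank": [ps.rank[k] for k in ps.kmers],
             "scaled_gini": [ps.scaled_importance[k] for k in ps.kmers],
             "category": [ps.category[k] for k in ps.kmers]}
        ).to_csv(outdir / f"pcres_{tp}.tsv", sep="\t", index=False,
                 float_format="%.6g")
        manifest.record_file("select", outdir / f"pcres_{tp}.tsv",
                             rows=len(ps.kmers))

    # --- TFBM matching -------------------------------------------------
    t0 = _time.time()
    manifest.stage("match", config.seed)
    backgrounds = {
        fam: similarity.family_background(library, fam,
                                          scope=config.background_scope)
        for fam in {r.family for r in library}
    }
    matches = {
        p: similarity.match_tfbm(p, library, scope=config.background_scope,
                                 backgrounds=backgrounds)
        for p in all_pcres
    }
    rows = []
    for p, res in matches.items():
        top = res[0]
        rows.append((p, top.target, top.family, round(top.pcc, 4), top.offset,
                     top.orientation, round(top.background_p95, 4),
                     top.significant))
    pd.DataFrame(rows, columns=["pcre", "tf", "family", "pcc", "offset",
                                "orientation", "background_p95",
                                "significant"]).to_csv(
        outdir / "tfbm_matches.tsv", sep="\t", index=False)
    manifest.record_file("match", outdir / "tfbm_matches.tsv", rows=len(rows))
    manifest.data["wall_time_s"]["match"] = round(_time.time() - t0, 2)

    # --- clustering ----------------------------------------------------
    t0 = _time.time()
    manifest.stage("cluster", config.seed)
    if len(all_pcres) >= 2:
        dist = distance_matrix(all_pcres)
        clusters = upgma_cut(dist, cutoff=config.cluster_cutoff,
                             labels=all_pcres)
        scaled = {tp: ps.scaled_importance for tp, ps in pcre_sets.items()}
        cluster_summary(clusters, categories, scaled, matches,
                        time_points=tps)
        pd.DataFrame(
            [(m, c.cluster_id) for c in clusters for m in c.members],
            columns=["kmer", "cluster_id"],
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        with open(outdir / "upgma_tree.nwk", "w") as fh:
            fh.write(to_newick(dist, all_pcres) + "\n")
        _write_cluster_summary(clusters, outdir / "cluster_summary.tsv", tps)
        manifest.record_file("cluster", outdir / "clusters.tsv",
                             rows=len(all_pcres))
        manifest.record_file("cluster", outdir / "cluster_summary.tsv")
        log.info("cluster: %d pCREs -> %d clusters", len(all_pcres),
                 len(clusters))
    else:
        clusters = []
    manifest.data["wall_time_s"]["cluster"] = round(_time.time() - t0, 2)

    # --- enrichment ----------------------------------------------------
    t0 = _time.time()
    manifest.stage("enrich", config.seed)
    annotations = {g.gene_id: g.go_terms for g in genes}
    background = {g.gene_id for g in genes}
    two_sided = config.test_sidedness == "two-sided"
    go_frames = []
    for tp in tps:
        study = labels[tp].up_genes
        if study:
            df = enrich.go_enrichment(study, background, annotations,
                                      alpha=config.alpha, two_sided=two_sided)
            df.insert(0, "time", tp)
            go_frames.append(df)
    if go_frames:
        pd.concat(go_frames, ignore_index=True).to_csv(
            outdir / "go_enrichment.tsv", sep="\t", index=False,
            float_format="%.4g")
        manifest.record_file("enrich", outdir / "go_enrichment.tsv")

    # pCRE presence enrichment in up-regulated genes, per time point
    pcre_frames = []
    for tp in tps:
        if tp not in minimal_sets:
            continue
        lab = labels[tp]
        ids = sorted(lab.up_genes | lab.negatives)
        X = index.presence_matrix(ids, minimal_sets[tp])
        presence = pd.DataFrame(X, index=ids, columns=minimal_sets[tp])
        df = enrich.pcre_upregulated_enrichment(presence, lab.up_genes,
                                                lab.negatives,
                                                two_sided=two_sided)
        df.insert(0, "time", tp)
        pcre_frames.append(df)
    if pcre_frames:
        pd.concat(pcre_frames, ignore_index=True).to_csv(
            outdir / "pcre_enrichment.tsv", sep="\t", index=False,
            float_format="%.4g")
        manifest.record_file("enrich", outdir / "pcre_enrichment.tsv")
    manifest.data["wall_time_s"]["enrich"] = round(_time.time() - t0, 2)

    _write_reports(reports, outdir, manifest)
    manifest.save()
    log.info("run complete: %s", outdir)
    return outdir


def _write_reports(reports, outdir: Path, manifest: RunManifest) -> None:
    payload = {
        tp: {
            "time": r.time, "direction": r.direction,
            "best_hyperparameters": r.best_hyperparameters,
            "cv_f1_folds": r.cv_f1_folds, "cv_f1": r.cv_f1,
            "test_f1": r.test_f1, "degenerate": r.degenerate,
        }
        for tp, r in reports.items()
    }
    with open(outdir / "model_reports.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    manifest.record_file("train", outdir / "model_reports.json")


def _write_cluster_summary(clusters, path: Path, tps) -> None:
    rows = []
    for c in clusters:
        row = {"cluster_id": c.cluster_id, "n_members": len(c.members),
               "members": ",".join(c.members)}
        for cat, frac in c.category_fractions.items():
            row[f"frac_{cat}"] = round(frac, 4)
        for tp in tps:
            v = c.median_scaled_importance.get(tp)
            row[f"median_imp_{tp}"] = "" if v is None else round(v, 4)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
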