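"""End-to-end orchestration of the diagnostic-gene discovery workflow.

One :class:`RunConfig` drives the chain simulate -> preprocess -> merge +
batch-correct -> differential expression -> co-expression modules ->
gene-set intersection -> model benchmark -> evaluation, writing every
stage artifact plus a machine-readable ``summary.json``. A single master
seed deterministically derives per-stage seeds so stages can be rerun in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coexpr, dge, genesets, io, metrics, preprocess
from .bench import enumerate_configs, run_benchmark
from .simulate import TREAT, SimConfig, simulate_cohorts

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_discovery"]

logger = logging.getLogger("mitodx")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All stage parameters of one discovery run, with study defaults."""

    # simulation
    n_train_cohorts: int = 3
    n_validation_cohorts: int = 3
    sim: dict = field(default_factory=dict)  # overrides for SimConfig fields
    # preprocessing
    knn_k: int = 10
    skip_combat: bool = False
    # differential expression
    lfc_min: float = 1.5
    fdr: float = 0.05
    # co-expression
    sd_min: float = 0.5
    min_module_size: int = 60
    r2_target: float = 0.85
    # benchmark / evaluation
    run_bench: bool = True
    min_features: int = 2
    threshold: float = 0.5
    manifest: str | None = None
    # bookkeeping
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if self.n_train_cohorts < 2:
            raise PipelineError("n_train_cohorts must be >= 2 (merging requires several cohorts)")
        if self.n_validation_cohorts < 1:
            raise PipelineError("n_validation_cohorts must be >= 1")
        if not 0 < self.fdr < 1:
            raise PipelineError(f"fdr must be in (0, 1), got {self.fdr}")
        if self.lfc_min < 0:
            raise PipelineError(f"lfc_min must be >= 0, got {self.lfc_min}")
        if self.sd_min < 0:
            raise PipelineError(f"sd_min must be >= 0, got {self.sd_min}")
        if self.min_module_size < 1:
            raise PipelineError(f"min_module_size must be >= 1, got {self.min_module_size}")
        if not 0 <= self.threshold <= 1:
            raise PipelineError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.knn_k < 1:
            raise PipelineError(f"knn_k must be >= 1, got {self.knn_k}")
        sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
        unknown = set(self.sim) - sim_fields
        if unknown:
            raise PipelineError(f"unknown sim keys: {sorted(unknown)}")


def validate_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise PipelineError("run config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (zlib.crc32(stage.encode()) ^ (master & 0xFFFFFFFF)) % (2**31)


class _EventLog:
    def __init__(self, path: Path | None):
        self.path = path
        if path is not None:
            path.write_text("")

    def __call__(self, stage: str, **fields) -> None:
        logger.info("%s %s", stage, fields)
        if self.path is not None:
            with self.path.open("a") as fh:
                fh.write(json.dumps({"ts": time.time(), "stage": stage, **fields}) + "\n")


def _preprocess_cohort(matrix: pd.DataFrame, knn_k: int) -> pd.DataFrame:
    if matrix.isna().to_numpy().any():
        matrix = preprocess.knn_impute(matrix, k=knn_k)
    matrix, _ = preprocess.auto_log2(matrix)
    return preprocess.quantile_normalize(matrix)


def run_discovery(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full discovery workflow; returns the run summary dict.

    Raises :class:`PipelineError` naming the failing stage on any error.
    """
    config.validate()
    out = Path(out_dir or config.out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    log = _EventLog(out / "events.jsonl")
    summary: dict = {"seed": config.seed}

    def _stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            log(name, status="failed", error=str(exc))
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        log(name, status="ok", seconds=round(time.time() - t0, 2))
        return result

    # --- simulate -----------------------------------------------------
    def do_simulate():
        sim_cfg = SimConfig(
            n_cohorts=config.n_train_cohorts + config.n_validation_cohorts,
            seed=stage_seed(config.seed, "simulate"),
            **config.sim,
        )
        return simulate_cohorts(sim_cfg), sim_cfg

    (matrices, pheno, truth), sim_cfg = _stage("simulate", do_simulate)
    cohorts = list(pheno["cohort"].unique())
    train_cohorts = cohorts[: config.n_train_cohorts]
    valid_cohorts = cohorts[config.n_train_cohorts :]
    group_of = pheno.set_index("sample_id")["group"]

    # --- per-cohort preprocessing ------------------------------------
    def do_preprocess():
        return [_preprocess_cohort(m, config.knn_k) for m in matrices]

    prepped = _stage("preprocess", do_preprocess)
    for cohort, m in zip(cohorts, prepped):
        io.write_matrix(m, out / f"{cohort}.normalised.tsv")
    io.write_phenotype(pheno, out / "phenotype.tsv")

    # --- merge + batch correction (training cohorts) ------------------
    def do_merge():
        merged, cohort_of = preprocess.merge_cohorts(
            prepped[: config.n_train_cohorts], train_cohorts
        )
        if config.skip_combat:
            return merged, cohort_of
        group = group_of.loc[merged.columns]
        corrected = preprocess.combat_adjust(merged, cohort_of, group)
        return corrected, cohort_of

    train_mat, cohort_of = _stage("merge", do_merge)
    io.write_matrix(train_mat, out / "training.merged.tsv")
    scores, explained = preprocess.pca_scores(train_mat)
    scores.assign(cohort=cohort_of.loc[scores.index]).to_csv(out / "training.pca.tsv", sep="\t")
    summary["pca_explained"] = [float(e) for e in explained]

    # --- differential expression --------------------------------------
    def do_dge():
        table = dge.run_dge(train_mat, group_of)
        up, down = dge.filter_degs(table, lfc_min=config.lfc_min, fdr=config.fdr)
        return table, up, down

    dge_table, up, down = _stage("dge", do_dge)
    dge_table.to_csv(out / "dge.tsv", sep="\t")
    deg_set = genesets.GeneSet("degs", tuple(sorted(set(up.genes) | set(down.genes))))
    summary["n_deg_up"], summary["n_deg_down"] = len(up), len(down)

    # --- co-expression modules ----------------------------------------
    def do_wgcna():
        variable = coexpr.filter_variable_genes(train_mat, sd_min=config.sd_min)
        beta, scan = coexpr.pick_soft_threshold(variable, r2_target=config.r2_target)
        adj = coexpr.adjacency(variable, beta)
        tom = coexpr.tom_similarity(adj)
        partition = coexpr.cluster_modules(tom, min_module_size=config.min_module_size)
        if (partition != coexpr.GREY).sum() == 0:
            raise PipelineError("no co-expression modules found")
        mes = coexpr.module_eigengenes(variable, partition)
        trait = (group_of.loc[variable.columns] == TREAT).astype(float)
        mt = coexpr.module_trait_correlation(mes, trait)
        key = coexpr.select_key_module(mt, partition)
        gsmm = coexpr.gene_significance_membership(variable, trait, partition, mes)
        return beta, scan, partition, mt, key, gsmm

    beta, scan, partition, mt, key_module, gsmm = _stage("wgcna", do_wgcna)
    scan.to_csv(out / "soft_threshold_scan.tsv", sep="\t", index=False)
    partition.rename("module").to_frame().to_csv(out / "modules.tsv", sep="\t")
    mt.assign(size=partition.value_counts().reindex(mt.index).fillna(0).astype(int)).to_csv(
        out / "module_trait.tsv", sep="\t"
    )
    gsmm.to_csv(out / "gene_significance.tsv", sep="\t")
    summary["soft_threshold"] = int(beta)
    summary["key_module"] = key_module
    summary["key_module_r"] = float(mt.loc[key_module, "r"])
    summary["key_module_p"] = float(mt.loc[key_module, "p"])

    # --- intersection funnel ------------------------------------------
    def do_intersect():
        module_set = genesets.GeneSet(
            key_module, tuple(sorted(partition.index[partition == key_module]))
        )
        mito_set = genesets.GeneSet("mito", tuple(sorted(truth.mito_genes)))
        hub, venn = genesets.intersect_hub(deg_set, module_set, mito_set)
        return hub, venn

    hub, venn = _stage("intersect", do_intersect)
    (out / "hub_genes.tsv").write_text("symbol\n" + "\n".join(hub.genes) + "\n")
    summary["venn"] = venn
    summary["hub_genes"] = list(hub.genes)
    summary["truth"] = {
        "n_de": len(truth.de_genes),
        "n_mito": len(truth.mito_genes),
        "n_funnel": len(truth.funnel_genes),
        "funnel_recovered": len(truth.funnel_genes & set(hub.genes)),
    }

    # --- benchmark -----------------------------------------------------
    if config.run_bench:
        if len(hub.genes) < config.min_features:
            raise PipelineError(
                f"hub gene set too small for modelling ({len(hub.genes)} genes); "
                "nothing to benchmark"
            )

        def do_bench():
            feats = list(hub.genes)
            Xtr = train_mat.loc[feats].T
            ytr = (group_of.loc[Xtr.index] == TREAT).astype(int).to_numpy()
            validations = {}
            for cohort, m in zip(cohorts, prepped):
                if cohort not in valid_cohorts:
                    continue
                missing = [f for f in feats if f not in m.index]
                if missing:
                    raise PipelineError(
                        f"validation cohort {cohort} lacks hub genes: {missing[:5]}"
                    )
                Xv = m.loc[feats].T
                yv = (group_of.loc[Xv.index] == TREAT).astype(int).to_numpy()
                validations[cohort] = (Xv, yv)
            manifest = None
            if config.manifest:
                manifest = yaml.safe_load(Path(config.manifest).read_text())
            configs = enumerate_configs(manifest)
            table, ranked = run_benchmark(
                configs, Xtr, ytr, validations,
                seed=stage_seed(config.seed, "bench"), min_features=config.min_features,
            )
            return table, ranked, Xtr, ytr, validations

        table, ranked, Xtr, ytr, validations = _stage("bench", do_bench)
        table.to_csv(out / "benchmark.tsv", sep="\t", index=False)
        top = ranked[0]
        summary["n_configs"] = len(ranked)
        summary["top_model"] = {
            "label": top.label,
            "mean_validation_auc": top.mean_auc,
            "train_auc": top.train_auc,
            "cohort_auc": top.cohort_auc,
            "n_selected": top.n_selected,
            "features": top.features,
        }

        # --- evaluation of the top model ------------------------------
        def do_evaluate():
            results = {}
            sets = {"training": (Xtr, ytr)}
            sets.update(validations)
            for name, (X, y) in sets.items():
                p = top.fitted.predict_proba(X)
                roc = metrics.auc_ci(p, y)
                cm = metrics.confusion_at_threshold(p, y, threshold=config.threshold)
                rates = metrics.confusion_rates(cm)
                results[name] = {
                    "auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
                    "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn, **rates,
                }
            return results

        summary["evaluation"] = _stage("evaluate", do_evaluate)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
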