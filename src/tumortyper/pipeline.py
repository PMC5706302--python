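"""Pipeline orchestration: config, staged execution, artefacts, report.

``run_pipeline`` drives build -> split -> rank (per repeat) -> accuracy
curve / per-class metrics -> stability selection -> final holdout
validation, writing every artefact (with the effective config and all
seeds echoed) into a run directory so a report can be regenerated from
the files alone. Re-running with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .evaluation import accuracy_curve, classwise_metrics, make_split_plan
from .matrix import (LabeledDataset, build_cna_matrix, build_spm_matrix,
                     concat_matrices, filter_gene_list, sanitize_matrix)
from .rankers import fit_predict_svm, svm_rfe_rank, tune_svm_cost
from .stability import final_validate, stability_select
from .synthetic import SyntheticConfig, generate_dataset
from .experiments import subset_block

__all__ = ["PipelineConfig", "run_pipeline", "write_report", "load_config"]

DEFAULT_SIZE_GRID = (10, 20, 50, 70, 100, 200, 300, 500, 700, 900)


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    ``mode`` selects the feature block: only somatic point mutations
    ('spm'), only copy-number alterations ('cna'), or both ('combined').
    When ``calls_path`` is unset, data come from the bundled synthetic
    generator configured by the ``synthetic`` block.
    """

    out_dir: str = "runs/run"
    mode: str = "combined"
    seed: int = 0
    n_repeats: int = 50
    holdout_frac: float = 0.25
    train_frac: float = 0.8
    size_grid: tuple[int, ...] = DEFAULT_SIZE_GRID
    top_m: int = 50
    panel_size: int = 50
    svm_cost: float = 1.0
    tune_cost_grid: tuple[float, ...] = ()  # empty -> use svm_cost as-is
    # file inputs (optional; synthetic data used when calls_path is None)
    calls_path: str | None = None
    labels_path: str | None = None
    spm_genes_path: str | None = None
    cna_genes_path: str | None = None
    exclusion_path: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("spm", "cna", "combined"):
            raise ValueError("mode must be 'spm', 'cna' or 'combined'")
        if not (0.0 < self.holdout_frac < 1.0 and 0.0 < self.train_frac < 1.0):
            raise ValueError("fractions must lie in (0, 1)")
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")

    def to_dict(self) -> dict:
        def plain(x):
            if isinstance(x, tuple):
                return [plain(v) for v in x]
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            return x
        return plain(dataclasses.asdict(self))


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    syn = raw.pop("synthetic", None)
    cfg = PipelineConfig(**raw)
    if syn is not None:
        if "samples_per_class" in syn:
            syn["samples_per_class"] = tuple(syn["samples_per_class"])
        cfg = dataclasses.replace(cfg, synthetic=SyntheticConfig(**syn))
    return cfg


def _load_file_dataset(cfg: PipelineConfig) -> LabeledDataset:
    calls = tio.read_call_table(cfg.calls_path)
    exclusion = set(tio.read_gene_list(cfg.exclusion_path)) if cfg.exclusion_path else set()
    spm_genes = filter_gene_list(tio.read_gene_list(cfg.spm_genes_path), exclusion) \
        if cfg.spm_genes_path else filter_gene_list(
            sorted(calls.loc[calls["kind"] == "SPM", "gene"].unique()), exclusion)
    cna_genes = filter_gene_list(tio.read_gene_list(cfg.cna_genes_path), exclusion) \
        if cfg.cna_genes_path else filter_gene_list(
            sorted(calls.loc[calls["kind"] != "SPM", "gene"].unique()), exclusion)

    labels_df = None
    if cfg.labels_path:
        import pandas as pd
        labels_df = pd.read_csv(cfg.labels_path, sep="\t", dtype={"sample_id": str})
    samples = list(labels_df["sample_id"]) if labels_df is not None else None

    spm = build_spm_matrix(calls, spm_genes, samples=samples) if spm_genes else None
    cna = build_cna_matrix(calls, cna_genes, samples=samples) if cna_genes else None
    if cfg.mode == "spm" or cna is None:
        matrix = spm
    elif cfg.mode == "cna" or spm is None:
        matrix = cna
    else:
        cna, _ = sanitize_matrix(cna, drop_duplicate_columns=True)
        # column-level sanitisation may have dropped all-zero rows; restore
        # them so the two blocks share a sample set
        matrix = concat_matrices(spm, _restore_rows(cna, spm.sample_ids))
    clean, _ = sanitize_matrix(matrix, drop_duplicate_columns=(cfg.mode == "cna"))
    if labels_df is None:
        raise ValueError("labels_path is required for file-based input")
    label_of = dict(zip(labels_df["sample_id"], labels_df["class_id"]))
    labels = np.array([label_of[s] for s in clean.sample_ids], dtype=np.int64)
    return LabeledDataset(clean, labels)


def _restore_rows(m, sample_ids):
    """Re-insert all-zero rows dropped by column-level sanitisation so the
    CNA block can be concatenated with the SPM block sample-for-sample."""
    from .matrix import BinaryAlterationMatrix
    have = {s: i for i, s in enumerate(m.sample_ids)}
    values = np.zeros((len(sample_ids), m.n_features), dtype=np.uint8)
    for i, s in enumerate(sample_ids):
        if s in have:
            values[i] = m.values[have[s]]
    return BinaryAlterationMatrix(list(sample_ids), list(m.features), values)


def _build_dataset(cfg: PipelineConfig) -> LabeledDataset:
    if cfg.calls_path is None:
        syn = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
        dataset, truth = generate_dataset(syn)
        dataset = subset_block(dataset, truth, cfg.mode)
        clean, _ = sanitize_matrix(dataset.matrix)
        keep = {s: i for i, s in enumerate(dataset.matrix.sample_ids)}
        rows = np.array([keep[s] for s in clean.sample_ids])
        return LabeledDataset(clean, dataset.labels[rows])
    return _load_file_dataset(cfg)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full analysis and write artefacts to ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "log.jsonl"
    log_lines: list[dict] = []

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                record = {"stage": name, "status": "failed", "error": str(exc)}
                log_lines.append(record)
                log_path.write_text("\n".join(json.dumps(r) for r in log_lines) + "\n")
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log_lines.append({"stage": name, "status": "ok",
                              "seconds": round(time.perf_counter() - t0, 3)})
            return result
        return wrap

    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))

    dataset = stage("build")(lambda: _build_dataset(cfg))
    tio.write_matrix_tsv(dataset.matrix, out / "matrix.tsv")

    plan = stage("split")(lambda: make_split_plan(
        dataset.labels, holdout_frac=cfg.holdout_frac,
        n_repeats=cfg.n_repeats, train_frac=cfg.train_frac, seed=cfg.seed))

    def do_rank():
        rankings = []
        for r, (tr, _) in enumerate(plan.repeats):
            train = dataset.subset_samples(tr)
            cost = cfg.svm_cost
            if cfg.tune_cost_grid:
                cost = tune_svm_cost(train, cfg.tune_cost_grid)
            rankings.append(svm_rfe_rank(train, cost=cost))
        return rankings
    rankings = stage("rank")(do_rank)
    for r, ranking in enumerate(rankings):
        tio.write_ranking_tsv(ranking, dataset.matrix.features,
                              out / f"ranking_{r:03d}.tsv")

    def do_curve():
        sizes = [s for s in cfg.size_grid if s <= dataset.matrix.n_features]
        if not sizes:
            sizes = [dataset.matrix.n_features]
        return accuracy_curve(rankings, sizes, plan, dataset, cost=cfg.svm_cost)
    curve = stage("curve")(do_curve)
    tio.write_curve_tsv(curve, out / "curve.tsv")

    stab = stage("stability")(lambda: stability_select(
        rankings,
        top_m=min(cfg.top_m, min(len(r) for r in rankings)),
        panel_size=min(cfg.panel_size, min(len(r) for r in rankings))))
    tio.write_stability_tsv(stab, dataset.matrix.features, out / "stability.tsv")

    metrics = stage("validate")(lambda: final_validate(
        stab.panel, dataset, plan, cost=cfg.svm_cost))
    tio.write_metrics_tsv(metrics, out / "metrics.tsv")

    kind_of = {f.feature_id: f.kind for f in dataset.matrix.features}
    summary = {
        "seed": cfg.seed,
        "mode": cfg.mode,
        "n_samples": dataset.matrix.n_samples,
        "n_features": dataset.matrix.n_features,
        "n_repeats": cfg.n_repeats,
        "panel": stab.panel,
        "panel_spm": sum(kind_of[f] == "SPM" for f in stab.panel),
        "panel_cna": sum(kind_of[f] in ("AMP", "DEL") for f in stab.panel),
        "holdout_accuracy": metrics.accuracy,
    }
    (out / "validation.json").write_text(json.dumps(summary, indent=2) + "\n")

    for rec in log_lines:
        rec.setdefault("checksums", {})
    log_lines.append({"stage": "artefacts", "checksums": {
        p.name: _checksum(p) for p in sorted(out.glob("*.tsv"))}})
    log_path.write_text("\n".join(json.dumps(r) for r in log_lines) + "\n")
    write_report(out)
    return out


def write_report(run_dir: str | Path) -> Path:
    """Regenerate the human-readable summary purely from run artefacts."""
    import pandas as pd
    run_dir = Path(run_dir)
    summary = json.loads((run_dir / "validation.json").read_text())
    curve = pd.read_csv(run_dir / "curve.tsv", sep="\t")
    metrics = pd.read_csv(run_dir / "metrics.tsv", sep="\t")
    stab = pd.read_csv(run_dir / "stability.tsv", sep="\t")
    sel = stab[stab["selected"]]

    lines = [
        "tumortyper run report",
        "=====================",
        f"mode: {summary['mode']}   seed: {summary['seed']}   "
        f"samples: {summary['n_samples']}   features: {summary['n_features']}   "
        f"repeats: {summary['n_repeats']}",
        "",
        "Accuracy vs panel size (mean over repeats, 95% CI half-width):",
    ]
    for _, row in curve.iterrows():
        lines.append(f"  n={int(row['n_features']):5d}  "
                     f"acc={row['mean_accuracy']:.4f} +/- {row['ci_halfwidth']:.4f}")
    lines += ["", "Per-class precision/recall on the holdout:"]
    for _, row in metrics.iterrows():
        lines.append(f"  class {int(row['class_id']):3d}  "
                     f"precision={row['precision']:.3f}  recall={row['recall']:.3f}  "
                     f"support={int(row['support'])}")
    n_spm = int((sel["kind"] == "SPM").sum())
    n_cna = int(sel["kind"].isin(["AMP", "DEL"]).sum())
    lines += [
        "",
        f"Selected panel ({len(sel)} features): {n_spm} SPM, {n_cna} CNA",
        f"Holdout accuracy with selected panel: {summary['holdout_accuracy']:.4f}",
        "",
    ]
    for _, row in sel.iterrows():
        lines.append(f"  {row['gene']}|{row['kind']}  frequency={int(row['frequency'])}"
                     f"  mean_rank={row['mean_rank']:.1f}")
    path = run_dir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
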