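"""End-to-end orchestration: panel -> pattern vectors -> t-SNE sweep ->
mixture clustering -> survival comparison -> driver ranking -> optional
sequential refinement, all driven by one structured config and one master
seed (stage seeds are derived deterministically, so stages can be re-run in
isolation)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clustering import assign_clusters
from .drivers import rank_drivers, top_k
from .embedding import (
    SWEEP_LEARNING_RATES,
    SWEEP_PERPLEXITIES,
    holdout_confirm,
    sweep_and_select,
)
from .io import (
    _SCALES,
    load_reference_panels,
    read_expression,
    read_panels,
    read_phenotype,
)
from .pattern_space import pattern_vectors_for_panel
from .stratify import sequential_refine
from .survival import compare_clusters
from .utils import derive_seed

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    expression: str
    phenotype: str
    panel: str
    panels_file: str | None = None  # None -> bundled reference registry
    scale: str = "log2p1"
    transpose: bool = False
    work_on_log_scale: bool = False
    allow_missing: bool = False
    grid: list[list[float]] | None = None  # [[perplexity, learning_rate], ...]
    silhouette_threshold: float = 0.35
    min_cluster_frac: float = 0.02
    min_group_size: int = 5
    importance_threshold: float = 1.0
    n_top_drivers: int = 6
    refine_panel: str | None = None
    refine_clusters: list[int] | None = None  # None -> all clusters
    seed: int = 0
    out_dir: str = "."

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def validate_config(config: RunConfig) -> list[str]:
    """Collect every problem with the config (paths, ranges, enums)."""
    errors: list[str] = []
    for attr in ("expression", "phenotype"):
        path = getattr(config, attr)
        if not path or not Path(path).exists():
            errors.append(f"{attr}: file not found: {path!r}")
    if config.panels_file is not None and not Path(config.panels_file).exists():
        errors.append(f"panels_file: file not found: {config.panels_file!r}")
    if config.scale not in _SCALES:
        errors.append(f"scale: must be one of {_SCALES}, got {config.scale!r}")
    if not config.panel:
        errors.append("panel: name required")
    if config.grid is not None:
        for i, point in enumerate(config.grid):
            if len(point) != 2:
                errors.append(f"grid[{i}]: expected [perplexity, learning_rate]")
                continue
            perp, lr = point
            if not (min(SWEEP_PERPLEXITIES) <= perp <= max(SWEEP_PERPLEXITIES)):
                errors.append(
                    f"grid[{i}]: perplexity {perp} outside sweep range "
                    f"[{min(SWEEP_PERPLEXITIES)}, {max(SWEEP_PERPLEXITIES)}]"
                )
            if lr not in SWEEP_LEARNING_RATES:
                errors.append(
                    f"grid[{i}]: learning rate {lr} not in {SWEEP_LEARNING_RATES}"
                )
    if not 0.0 <= config.silhouette_threshold <= 1.0:
        errors.append("silhouette_threshold: must lie in [0, 1]")
    if config.min_group_size < 1:
        errors.append("min_group_size: must be >= 1")
    if not isinstance(config.seed, int):
        errors.append("seed: must be an integer")
    return errors


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunReport:
    status: str  # "ok" | "rejected" | "failed"
    config_hash: str
    seed: int
    version: str = __version__
    failed_stage: str | None = None
    error: str | None = None
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_all(config: RunConfig) -> RunReport:
    """Execute all stages in order, writing intermediate artifacts to
    ``config.out_dir``; a discernibility rejection stops the run with status
    "rejected", and a stage error yields status "failed" with the stage name
    (artifacts produced so far are kept)."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(status="ok", config_hash=config_hash(config), seed=config.seed)
    stage = "load"
    try:
        registry = (
            read_panels(config.panels_file) if config.panels_file else load_reference_panels()
        )
        panel = registry.get(config.panel)
        expr = read_expression(config.expression, scale=config.scale, transpose=config.transpose)
        pheno = read_phenotype(config.phenotype)
        report.stages["load"] = {
            "n_samples": expr.n_samples,
            "n_genes": expr.n_genes,
            "panel": panel.name,
            "panel_size": panel.n,
        }

        stage = "pattern_space"
        vectors = pattern_vectors_for_panel(
            expr, panel,
            work_on_log_scale=config.work_on_log_scale,
            allow_missing=config.allow_missing,
        )
        report.stages["pattern_space"] = {"n": vectors.n}

        stage = "embedding"
        grid = [tuple(p) for p in config.grid] if config.grid else None
        sweep = sweep_and_select(
            vectors, grid,
            seed=derive_seed(config.seed, "sweep"),
            silhouette_threshold=config.silhouette_threshold,
            min_cluster_frac=config.min_cluster_frac,
        )
        report.stages["embedding"] = {
            "records": [asdict(r) for r in sweep.records],
            "rejected": sweep.rejected,
        }
        if sweep.rejected:
            report.status = "rejected"
            _write_report(report, out)
            return report
        report.stages["embedding"].update(
            {
                "k": sweep.k,
                "perplexity": sweep.params.perplexity,
                "learning_rate": sweep.params.learning_rate,
                "validity": sweep.validity,
                "validation_ks": sweep.validation_ks,
                "kl_divergence": sweep.embedding.kl_divergence,
            }
        )
        _write_coords(sweep.embedding, out / "coords.tsv")

        stage = "clustering"
        solution, attempts = assign_clusters(
            sweep.embedding, sweep.k, sweep.reference_labels,
            derive_seed(config.seed, "gmm"),
        )
        report.stages["clustering"] = {
            "k": solution.k,
            "chosen_config": solution.config.label,
            "unity_score": solution.unity_score,
            "attempts": [
                {"config": a.config.label, "unity_score": a.unity_score} for a in attempts
            ],
        }
        _write_labels(solution, out / "labels.tsv")

        stage = "holdout"
        agreement = holdout_confirm(
            vectors, solution.labels, derive_seed(config.seed, "holdout"),
            params=sweep.params,
        )
        report.stages["holdout"] = {"agreement": agreement}

        stage = "survival"
        labels_by_sample = dict(zip(solution.sample_ids, (int(l) for l in solution.labels)))
        surv = compare_clusters(labels_by_sample, pheno, min_group_size=config.min_group_size)
        report.stages["survival"] = surv.to_dict()

        stage = "drivers"
        table = rank_drivers(vectors, solution.labels, derive_seed(config.seed, "drivers"))
        table.prominence_threshold = config.importance_threshold
        report.stages["drivers"] = {
            "top": top_k(table, min(config.n_top_drivers, len(table.gene_ids))),
            "prominent": [g for g, p in zip(table.gene_ids, table.prominent) if p],
            "importance": dict(zip(table.gene_ids, table.importance)),
        }
        _write_importance(table, out / "drivers.tsv")

        if config.refine_panel:
            stage = "refine"
            panel2 = registry.get(config.refine_panel)
            targets = config.refine_clusters or sorted(set(solution.labels.tolist()))
            refinements = {}
            for c in targets:
                res = sequential_refine(
                    expr, pheno, solution, panel2, int(c),
                    seed=derive_seed(config.seed, f"refine{c}"),
                    grid=grid,
                    min_group_size=config.min_group_size,
                    work_on_log_scale=config.work_on_log_scale,
                    allow_missing=config.allow_missing,
                )
                refinements[str(c)] = {
                    "status": res.status,
                    "n_subset": res.n_subset,
                    "k": res.k,
                    "headline_p": None if res.survival is None else res.survival.headline_p,
                    "significant": res.significant,
                    "reason": res.reason,
                }
            report.stages["refine"] = {"panel2": panel2.name, "clusters": refinements}
    except Exception as err:  # noqa: BLE001 - stage name is part of the contract
        report.status = "failed"
        report.failed_stage = stage
        report.error = f"{type(err).__name__}: {err}"
        logger.exception("pipeline failed at stage %s", stage)
    _write_report(report, out)
    return report


def _write_coords(embedding, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tx\ty\tz\n")
        for sid, row in zip(embedding.sample_ids, embedding.coords):
            fh.write(f"{sid}\t{row[0]!r}\t{row[1]!r}\t{row[2]!r}\n")


def _write_labels(solution, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcluster\n")
        for sid, lab in zip(solution.sample_ids, solution.labels):
            fh.write(f"{sid}\t{lab}\n")


def _write_importance(table, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\timportance\tprominent\n")
        for gene, imp in table.ranked():
            fh.write(f"{gene}\t{imp!r}\t{int(imp > table.prominence_threshold)}\n")


def _write_report(report: RunReport, out: Path) -> None:
    (out / "report.json").write_text(report.to_json() + "\n")
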