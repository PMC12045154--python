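"""End-to-end orchestration: intersect -> normalize -> ACOSG -> train -> predict.

A :class:`RunConfig` captures every knob of a run; the resolved config is
written next to the outputs so any run can be reproduced from its output
directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .acosg import AttentionConfig, score_genes
from .classifier import (
    CellTypeProbabilityMatrix,
    TrainingConfig,
    build_network,
    hard_labels,
    predict,
    save_model,
    train,
)
from .core_data import (
    ExpressionDataset,
    encode_labels,
    intersect_genes,
    normalize,
    write_probability_matrix,
)
from .evaluation import (
    EvaluationReport,
    ReferenceMap,
    build_reference_map,
    confusion_matrix,
    evaluate_methods,
)

logger = logging.getLogger("dsct")

__all__ = ["RunConfig", "PipelineResult", "run_full_pipeline", "run_benchmark"]


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    reference_path: str = ""
    spatial_path: str = ""
    output_dir: str = "dsct_out"
    labels_col: str = "cell_type"
    # normalization
    target_sum: float = 1e4
    log_transform: bool = True
    # ACOSG
    mu: float = 1.0
    n_top: int = 50
    per_type: bool = True
    attention_epochs: int = 30
    attention_lr: float = 0.01
    # network overrides (None = module defaults)
    hidden_dims: tuple[int, ...] | None = None
    dropout_rate: float | None = None
    # training
    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 128
    validation_fraction: float = 0.1
    early_stop_patience: int = 10
    # evaluation
    evaluate_against_truth: bool = False
    truth_labels_path: str | None = None
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if d["hidden_dims"] is not None:
            d["hidden_dims"] = list(d["hidden_dims"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if d.get("hidden_dims") is not None:
            d["hidden_dims"] = tuple(d["hidden_dims"])
        return cls(**d)

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            validation_fraction=self.validation_fraction,
            seed=self.seed,
            early_stop_patience=self.early_stop_patience,
        )

    def attention_config(self) -> AttentionConfig:
        return AttentionConfig(
            epochs=self.attention_epochs, learning_rate=self.attention_lr, seed=self.seed
        )


@dataclass
class PipelineResult:
    probabilities: CellTypeProbabilityMatrix
    labels: list[str]
    panel: list[str]
    output_dir: Path
    report: EvaluationReport | None = None


def run_full_pipeline(
    cfg: RunConfig,
    reference: ExpressionDataset | None = None,
    spatial: ExpressionDataset | None = None,
) -> PipelineResult:
    """Execute the whole label-transfer workflow and write all artifacts.

    Datasets can be passed in memory (tests, simulations) or read from the
    configured paths. Stages: gene intersection, normalization, ACOSG panel
    selection, classifier training, prediction, optional evaluation against
    known truth labels.
    """
    from .core_data import read_dataset  # local import to keep module load light

    t0 = time.perf_counter()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("[%s] %.1fs elapsed", name, time.perf_counter() - t0)

    if reference is None:
        reference = read_dataset(cfg.reference_path, labels_col=cfg.labels_col)
    if spatial is None:
        spatial = read_dataset(cfg.spatial_path)

    stage("intersect")
    reference, spatial = intersect_genes(reference, spatial)

    stage("normalize")
    ref_norm = normalize(reference, cfg.target_sum, cfg.log_transform)
    sp_norm = normalize(spatial, cfg.target_sum, cfg.log_transform)

    stage("acosg")
    vocab, codes = encode_labels(ref_norm)
    table = score_genes(
        ref_norm, codes, vocab, mu=cfg.mu, n_top=cfg.n_top, attention=cfg.attention_config()
    )
    panel = table.select_panel(per_type=cfg.per_type)
    table.to_tsv(out / "gene_scores.tsv")
    (out / "panel.txt").write_text("\n".join(panel) + "\n")

    stage("train")
    overrides = {}
    if cfg.hidden_dims is not None:
        overrides["hidden_dims"] = cfg.hidden_dims
    if cfg.dropout_rate is not None:
        overrides["dropout_rate"] = cfg.dropout_rate
    spec = build_network(len(panel), len(vocab), **overrides)
    model = train(ref_norm.subset_genes(panel), codes, vocab, spec, cfg.training_config())
    save_model(model, out / "model")

    stage("predict")
    pm = predict(model, sp_norm)
    write_probability_matrix(pm, out / "probabilities.csv")
    labels = hard_labels(pm)
    (out / "labels.csv").write_text(
        "obs_id,cell_type\n" + "\n".join(f"{o},{l}" for o, l in zip(pm.obs_ids, labels)) + "\n"
    )

    report = None
    if cfg.evaluate_against_truth and cfg.truth_labels_path:
        stage("evaluate")
        truth = [
            line.split(",")[1]
            for line in Path(cfg.truth_labels_path).read_text().splitlines()[1:]
            if line
        ]
        cm, acc = confusion_matrix(labels, truth)
        cm.to_csv(out / "confusion_matrix.csv")
        (out / "accuracy.json").write_text(json.dumps({"overall_accuracy": acc}))

    cfg.to_yaml(out / "resolved_config.yaml")
    (out / "run_info.json").write_text(
        json.dumps(
            {"dsct_version": __version__, "seed": cfg.seed,
             "wall_time_s": round(time.perf_counter() - t0, 3)}
        )
    )
    return PipelineResult(pm, labels, panel, out, report)


def run_benchmark(
    predictions: dict[str, CellTypeProbabilityMatrix],
    ref: ReferenceMap,
    output_dir: str | Path | None = None,
) -> EvaluationReport:
    """Score >= 2 methods' probability matrices against one reference map."""
    for name, pm in predictions.items():
        if tuple(pm.vocab.types) != tuple(ref.vocab.types):
            raise ValueError(f"vocabulary of method {name!r} does not match reference")
    report = evaluate_methods(predictions, ref)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_tsv(out / "benchmark.tsv")
    return report
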