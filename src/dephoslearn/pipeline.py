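"""End-to-end recipes: configuration, seed fan-out, run directories,
and whole-protein prediction.

A run directory has a fixed layout (``datasets/``, ``models/``,
``reports/``, ``logs/``); every artifact is stamped with the config
hash and the global seed, and a rerun with the same config and seed
reproduces the reports bit for bit (single-threaded).  The global seed
fans out to per-stage seeds via ``stage_seed(seed, k)`` so any stage
can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import dataset_prep, evaluation, synthetic
from .encoding import build_encoding, encode_windows
from .model import ModelSpec, TrainedModel, build_model, load_model, save_model, train
from .records import RESIDUE_CLASSES, ProteinRecord, SiteDataset
from .transfer import ChainStage, run_chain

logger = logging.getLogger("dephoslearn")


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed derived from the one global seed."""
    return (global_seed * 1_000_003 + stage_index) % (2**31)


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    out_dir: str = "run"
    fasta: str | None = None
    sites: str | None = None
    residue_class: str = "ST"
    window_size: int = 31
    train_fraction: float = 0.8
    k_folds: int = 5
    seed: int = 0
    scale: float = 1.0
    model: dict = field(default_factory=dict)  # ModelSpec overrides
    epochs_source: int | None = None

    def __post_init__(self) -> None:
        if self.window_size % 2 == 0:
            raise ValueError(f"window size must be odd: {self.window_size}")
        if self.residue_class not in RESIDUE_CLASSES:
            raise ValueError(f"bad residue class: {self.residue_class}")

    def model_spec(self, seed: int | None = None, **overrides) -> ModelSpec:
        params = {"window_size": self.window_size, **self.model, **overrides}
        if seed is not None:
            params["seed"] = seed
        return ModelSpec(**params)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _setup_run_dir(config: RunConfig) -> Path:
    root = Path(config.out_dir)
    for sub in ("datasets", "models", "reports", "logs"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    stamp = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "started": datetime.now(timezone.utc).isoformat(),
    }
    (root / "logs" / "run.json").write_text(json.dumps(stamp, indent=2) + "\n")
    handler = logging.FileHandler(root / "logs" / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return root


def _report(report: evaluation.MetricsReport, path: Path) -> None:
    path.write_text(json.dumps(report.to_dict(), indent=2, default=float) + "\n")


def run_recipe(config: RunConfig) -> dict:
    """Synthetic end-to-end recipe: simulate -> train source ->
    transfer to ST target -> transfer to Y target -> evaluate each.

    Returns a dict with the trained models and their test reports;
    every artifact lands under the run directory.
    """
    root = _setup_run_dir(config)
    logger.info("recipe start: hash=%s seed=%d scale=%g",
                config.digest(), config.seed, config.scale)

    bundle = synthetic.emulate_corpus_shapes(
        stage_seed(config.seed, 0), scale=config.scale,
        window_size=config.window_size,
    )
    scheme = build_encoding()
    splits: dict[str, dict] = {}
    for k, (name, dataset) in enumerate(bundle.items()):
        dataset_prep.write_window_table(dataset, root / "datasets" / f"{name}.tsv")
        train_ds, test_ds = dataset_prep.split_train_test(
            dataset if dataset.stage == "balanced"
            else dataset.with_examples(dataset.examples, stage="balanced"),
            config.train_fraction,
            seed=stage_seed(config.seed, 10 + k),
        )
        splits[name] = {
            "train": encode_windows(train_ds, scheme),
            "test": encode_windows(test_ds, scheme),
        }
        logger.info("dataset %s: %d train / %d test windows",
                    name, len(train_ds), len(test_ds))

    spec = config.model_spec(seed=stage_seed(config.seed, 1))
    source_epochs = config.epochs_source or spec.epochs
    stages = [
        ChainStage("source", splits["source"]["train"]),
        ChainStage("st_target", splits["st_target"]["train"]),
        ChainStage("y_target", splits["y_target"]["train"]),
    ]
    # The source stage may use its own epoch budget.
    models = run_chain(
        stages, dataclasses.replace(spec, epochs=source_epochs),
        seed=config.seed,
    ) if source_epochs == spec.epochs else _run_chain_mixed_epochs(
        stages, spec, source_epochs, config.seed)

    results = {}
    for model, stage in zip(models, stages):
        save_model(model, root / "models" / stage.name)
        X_test, Y_test = splits[stage.name]["test"]
        scores = model.predict_proba(X_test)
        report = evaluation.evaluate_predictions(Y_test[:, 1], scores)
        _report(report, root / "reports" / f"{stage.name}.json")
        results[stage.name] = {"model": model, "report": report}
        logger.info("stage %s: test MCC %.3f AUC %.3f",
                    stage.name, report.mcc, report.roc_auc)
    return results


def _run_chain_mixed_epochs(stages, spec, source_epochs, seed):
    from .transfer import TransferPlan, fine_tune

    models = []
    src_spec = dataclasses.replace(spec, epochs=source_epochs,
                                   seed=stage_seed(seed, 0))
    source = build_model(src_spec)
    train(source, *stages[0].data, seed=stage_seed(seed, 0))
    source.lineage = [stages[0].name]
    models.append(source)
    for k, stage in enumerate(stages[1:], start=1):
        plan = TransferPlan(
            source=models[-1],
            target_spec=dataclasses.replace(
                models[-1].spec, epochs=spec.epochs, seed=stage_seed(seed, k)),
            target_data=stage.data,
            frozen_layers=stage.frozen_layers,
        )
        model = fine_tune(plan, seed=stage_seed(seed, k))
        model.lineage = models[-1].lineage + [stage.name]
        models.append(model)
    return models


def predict_fasta(
    model: TrainedModel,
    fasta_path: str | Path,
    residue_class: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every in-class residue with full flanks in a FASTA file.

    Returns (predictions, skipped): one prediction row per scoreable
    site (protein_id, position, residue, probability, call) and one
    skipped row per in-class residue whose flank does not fit.
    """
    proteins = dataset_prep.load_fasta(fasta_path)
    scheme = build_encoding()
    flank = (model.spec.window_size - 1) // 2
    class_residues = set(RESIDUE_CLASSES[residue_class])

    rows = []
    windows = []
    skipped = []
    for protein in proteins:
        for pos0, letter in enumerate(protein.sequence):
            if letter not in class_residues:
                continue
            pos = pos0 + 1
            if pos - flank < 1 or pos + flank > len(protein):
                skipped.append((protein.id, pos, letter, "incomplete flank"))
                continue
            windows.append(protein.sequence[pos - flank - 1 : pos + flank])
            rows.append((protein.id, pos, letter))

    if windows:
        X, _ = encode_windows(windows, scheme)
        probs = model.predict_proba(X)
    else:
        probs = []
    predictions = pd.DataFrame(
        [
            (pid, pos, res, float(p), "positive" if p >= 0.5 else "negative")
            for (pid, pos, res), p in zip(rows, probs)
        ],
        columns=["protein_id", "position", "residue", "probability", "call"],
    )
    skipped_df = pd.DataFrame(
        skipped, columns=["protein_id", "position", "residue", "reason"]
    )
    return predictions, skipped_df
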