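"""Two-step transfer learning: pre-train on a data-rich source task,
fine-tune on a small target task.

Weights (and only weights) move between tasks: the optimizer state and
the learning-rate schedule restart at every stage.  Layers may be
frozen by name during fine-tuning; the default — following the
published finding that retraining everything works best — freezes
nothing.  Chained transfers (e.g. phospho-ST -> dephospho-ST ->
dephospho-Y) carry provenance metadata so a model's full lineage can be
reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    ModelSpec,
    TrainedModel,
    architecturally_equal,
    build_model,
    train,
)


class TransferError(ValueError):
    """Raised when source and target are architecturally incompatible."""


@dataclass
class TransferPlan:
    source: TrainedModel
    target_spec: ModelSpec
    target_data: tuple[np.ndarray, np.ndarray]
    frozen_layers: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not architecturally_equal(self.source.spec, self.target_spec):
            raise TransferError(
                "source and target specs differ architecturally: "
                f"{self.source.spec.architecture()} vs "
                f"{self.target_spec.architecture()}"
            )
        known = set(self.source.layer_names())
        unknown = self.frozen_layers - known
        if unknown:
            raise TransferError(f"unknown frozen layers {sorted(unknown)}; "
                                f"model layers are {sorted(known)}")


def transfer_weights(source: TrainedModel, target: TrainedModel) -> TrainedModel:
    """Copy every parameter tensor from source into target; reset history.

    Architectures must match exactly — in particular the window size,
    because the flatten layer's width depends on the number of
    timesteps.  A shape mismatch is reported with the offending layer.
    """
    if not architecturally_equal(source.spec, target.spec):
        raise TransferError(
            "cannot transfer between architectures: source window "
            f"{source.spec.window_size} / target {target.spec.window_size}; "
            f"full specs {source.spec.architecture()} vs {target.spec.architecture()}"
        )
    src = source.get_weights()
    tgt = target.get_weights()
    for key in tgt:
        if src[key].shape != tgt[key].shape:
            raise TransferError(
                f"shape mismatch in layer {key.split('/')[0]!r}: "
                f"{src[key].shape} vs {tgt[key].shape}"
            )
    target.set_weights(src)
    target.history = {k: [] for k in ("loss", "accuracy", "val_loss",
                                      "val_accuracy", "lr")}
    target.best_epoch = -1
    target.lineage = list(source.lineage)
    return target


def fine_tune(plan: TransferPlan, seed: int | None = None,
              validation_fraction: float = 0.1) -> TrainedModel:
    """Instantiate a target model with the source weights and train it.

    Frozen layers keep their parameters bit-identical; everything else
    updates.  Training uses the same protocol as from-scratch training
    (checkpoint on validation accuracy, LR reduction on plateau) with a
    fresh Adam state.
    """
    X, Y = plan.target_data
    if len(X) == 0:
        raise ValueError("empty target data")
    target = build_model(plan.target_spec)
    transfer_weights(plan.source, target)
    all_layers = set(target.layer_names())
    if plan.frozen_layers >= all_layers and plan.target_spec.epochs > 0:
        import warnings

        warnings.warn("all layers frozen: fine-tuning cannot change the model",
                      stacklevel=2)
    train(target, X, Y, validation_fraction=validation_fraction, seed=seed,
          frozen_layers=plan.frozen_layers)
    return target


@dataclass
class ChainStage:
    """One stage of a transfer chain: a named dataset plus a freeze policy."""

    name: str
    data: tuple[np.ndarray, np.ndarray]
    frozen_layers: set[str] = field(default_factory=set)


def run_chain(stages: list[ChainStage], base_spec: ModelSpec,
              seed: int) -> list[TrainedModel]:
    """Train stage 1 from scratch, then fine-tune each later stage from
    its predecessor's best checkpoint.

    Per-stage seeds derive deterministically from the global seed so
    stages are individually reproducible.  Each returned model's
    ``lineage`` lists the stage names that produced it, in order.
    """
    if not stages:
        raise ValueError("chain needs at least one stage")
    models: list[TrainedModel] = []
    for k, stage in enumerate(stages):
        stage_seed = (seed * 1_000_003 + k) % (2**31)
        spec = base_spec.with_seed(stage_seed)
        if k == 0:
            model = build_model(spec)
            train(model, *stage.data, seed=stage_seed,
                  frozen_layers=stage.frozen_layers)
            model.lineage = [stage.name]
        else:
            plan = TransferPlan(
                source=models[-1],
                target_spec=spec,
                target_data=stage.data,
                frozen_layers=stage.frozen_layers,
            )
            model = fine_tune(plan, seed=stage_seed)
            model.lineage = models[-1].lineage + [stage.name]
        models.append(model)
    return models
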