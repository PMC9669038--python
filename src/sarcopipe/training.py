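"""Training of the model matrix: T training-set replicates x F CV folds.

Each cell (m, f) of the matrix is one binary slice classifier trained on the
augmented pool restricted to the learning patients of fold f, under the
replicate-specific random stream m. Per epoch, ``slices_per_epoch`` pool
entries are drawn without replacement (with replacement across epochs) and
materialized lazily into tumor-preserving crops. At full scale this is the
50-epoch x 35,000-slice schedule over a 875,000-entry pool, 24 x 6 = 144
models; desk-scale runs shrink every count but keep the structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentConfig, materialize
from .backbones import TinyCNN
from .cohort import POSITIVE_LABEL, CvAssignment, SliceRecord

__all__ = ["TrainConfig", "ModelMatrix", "train_model", "train_matrix"]


@dataclass
class TrainConfig:
    """Schedule and architecture of one training run.

    Defaults are the full-scale schedule (AMSGrad, learning rate 1e-4, 50
    epochs of 35,000 slices, 24 training sets x 6 folds); desk-scale runs
    override epochs, slices_per_epoch, n_training_sets, n_folds and use a
    larger learning rate suited to the small from-scratch CNN.
    """

    backbone: str = "tiny_cnn"
    input_size: tuple[int, int] = (224, 224)
    optimizer: str = "amsgrad"
    learning_rate: float = 1e-4
    epochs: int = 50
    slices_per_epoch: int = 35_000
    batch_size: int = 32
    n_training_sets: int = 24
    n_folds: int = 6
    channels: tuple[int, ...] = (8, 16, 32, 32)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.slices_per_epoch < 1:
            raise ValueError("epochs and slices_per_epoch must be positive")
        if self.n_training_sets < 1 or self.n_folds < 1:
            raise ValueError("n_training_sets and n_folds must be positive")
        if self.optimizer != "amsgrad":
            raise ValueError("only the AMSGrad optimizer is supported")
        if self.backbone not in ("tiny_cnn", "mobilenet_v2"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


@dataclass
class ModelMatrix:
    """Trained models indexed by (training set m, fold f), both 1-based."""

    models: dict[tuple[int, int], object]
    n_training_sets: int
    n_folds: int
    training_patients: dict[tuple[int, int], frozenset] = field(default_factory=dict)
    logs: dict[tuple[int, int], list[dict]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = self.n_training_sets * self.n_folds
        if len(self.models) != expected:
            raise ValueError(
                f"model matrix has {len(self.models)} cells, expected {expected}"
            )

    def model(self, m: int, f: int):
        return self.models[(m, f)]

    def save_logs(self, out_dir) -> None:
        out_dir = Path(out_dir)
        for (m, f), log in self.logs.items():
            cell = out_dir / f"M{m}" / f"fold{f}"
            cell.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(log).to_csv(cell / "training_log.csv", index=False)


def _materialize_batch(
    rows: pd.DataFrame,
    records_by_id: dict[str, SliceRecord],
    aug_config: AugmentConfig,
    input_size: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    images = np.empty((len(rows), *input_size, 3))
    labels = (rows["class"] == POSITIVE_LABEL).to_numpy(dtype=float)
    ids = rows["source_slice_id"].to_numpy()
    seeds = rows["transform_seed"].to_numpy()
    for i in range(len(rows)):
        rec = records_by_id[ids[i]]
        crop = materialize(rec, int(seeds[i]), aug_config, crop_size=input_size)
        images[i] = np.repeat(crop[:, :, None], 3, axis=2) / 255.0
    return images, labels


def train_model(
    pool: pd.DataFrame,
    records_by_id: dict[str, SliceRecord],
    config: TrainConfig,
    aug_config: AugmentConfig,
    seed: int = 0,
    log: list | None = None,
) -> TinyCNN:
    """Train one classifier on an (already fold-restricted) pool.

    Per epoch, ``min(slices_per_epoch, len(pool))`` entries are drawn without
    replacement and visited in batches; when the draw equals the pool size an
    epoch degenerates to one full pass in random order. Returns a model whose
    ``predict_proba`` yields a sarcoma probability per 3-channel crop.
    """
    if config.backbone != "tiny_cnn":
        raise ValueError(
            "only the tiny_cnn backbone is trainable in-process; mobilenet_v2 "
            "is exposed for architecture inspection and parameter counting"
        )
    if len(pool) < config.batch_size:
        raise ValueError(
            f"pool of {len(pool)} entries is smaller than one batch "
            f"({config.batch_size})"
        )
    rng = np.random.default_rng(seed)
    model = TinyCNN(
        input_size=config.input_size,
        channels=config.channels,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    n_draw = min(config.slices_per_epoch, len(pool))

    def sample_batches(_epoch: int):
        picks = rng.choice(len(pool), size=n_draw, replace=False)
        epoch_rows = pool.iloc[picks]
        for start in range(0, n_draw, config.batch_size):
            chunk = epoch_rows.iloc[start : start + config.batch_size]
            yield _materialize_batch(
                chunk, records_by_id, aug_config, config.input_size
            )

    model.fit_epochs(sample_batches, config.epochs, config.learning_rate, log=log)
    return model


def train_matrix(
    pool: pd.DataFrame,
    records: list[SliceRecord],
    assignment: CvAssignment,
    config: TrainConfig,
    aug_config: AugmentConfig,
) -> ModelMatrix:
    """Train the full T x F model matrix.

    For fold f the global pool is restricted to entries whose source patient
    is *not* in CV group f, so model (m, f) never sees fold-f patients; the
    training patient set of every cell is recorded for leakage audits.
    Training-set replicates m differ only in their random stream (epoch
    subsampling and weight initialization).
    """
    records_by_id = {r.slice_id: r for r in records}
    patient_of = {sid: r.patient_id for sid, r in records_by_id.items()}
    if config.n_folds == 1:
        warnings.warn(
            "n_folds=1: no held-out fold, the evaluation set is empty",
            stacklevel=2,
        )
    models: dict[tuple[int, int], object] = {}
    train_patients: dict[tuple[int, int], frozenset] = {}
    logs: dict[tuple[int, int], list[dict]] = {}
    for f in range(1, config.n_folds + 1):
        eval_patients = assignment.patients_in(f) if config.n_folds > 1 else set()
        keep = pool["source_slice_id"].map(patient_of).apply(
            lambda p: p not in eval_patients
        )
        pool_f = pool[keep].reset_index(drop=True)
        seen = frozenset(
            patient_of[sid] for sid in pool_f["source_slice_id"].unique()
        )
        for m in range(1, config.n_training_sets + 1):
            cell_seed = int(
                np.random.SeedSequence([config.seed, m, f]).generate_state(1)[0]
                % (2**31 - 1)
            )
            log: list[dict] = []
            try:
                models[(m, f)] = train_model(
                    pool_f, records_by_id, config, aug_config, seed=cell_seed, log=log
                )
            except ValueError as err:
                raise ValueError(f"training set M{m}, fold {f}: {err}") from err
            train_patients[(m, f)] = seen
            logs[(m, f)] = log
    return ModelMatrix(
        models=models,
        n_training_sets=config.n_training_sets,
        n_folds=config.n_folds,
        training_patients=train_patients,
        logs=logs,
    )
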