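"""2D U-Net segmentation: configuration, training, prediction and the
subject-level cross-validation harnesses.

The segmenter is a per-slice (2D) encoder–decoder network with skip
connections; scans are predicted slice by slice and re-assembled into a
mask volume.  Two cross-validation schemes operate strictly at subject
level so no slice (or augmented copy of it) from a test subject ever
enters training: leave-one-out over the cohort for evaluation, and k-fold
over the training subjects for learning-rate selection.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace

import numpy as np

from ._nn import Adam, UNet2D, segmentation_loss, sigmoid
from .core import MaskVolume, ScanVolume, TrainingDivergedError
from .preprocess import PreprocConfig, augment_rotations, preprocess_scan
from .volumetry import dice

__all__ = [
    "ModelConfig",
    "SplitPlan",
    "build_model",
    "build_training_set",
    "train",
    "predict_volume",
    "tune_learning_rate",
    "run_loocv",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Segmentation model and training hyperparameters.

    ``depth`` is the number of 2×2 down-samplings (the input side must be
    divisible by 2**depth; 256 satisfies the default depth 3).
    ``encoder_name`` selects plain conv blocks ("custom-small", the
    CPU-friendly default) or residual double-conv encoder blocks
    ("resnet34-style").  ``learning_rate`` may be "auto" to trigger 5-fold
    CV tuning.  ``threshold`` binarizes the per-pixel probabilities.
    Loss, optimizer and epoch budget are configuration with documented
    defaults: combined Dice + cross-entropy loss and Adam suit heavily
    class-imbalanced organ masks.
    """

    depth: int = 3
    base_channels: int = 8
    encoder_name: str = "custom-small"
    loss: str = "combined"
    epochs: int = 8
    batch_size: int = 8
    learning_rate: float | str = 1e-3
    seed: int = 0
    threshold: float = 0.5
    keep_empty_slices: bool = True

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.encoder_name not in ("custom-small", "resnet34-style"):
            raise ValueError("encoder_name must be 'custom-small' or 'resnet34-style'")
        if self.loss not in ("dice", "cross-entropy", "combined"):
            raise ValueError("loss must be dice | cross-entropy | combined")
        if self.learning_rate != "auto" and float(self.learning_rate) <= 0:
            raise ValueError("learning_rate must be > 0 or 'auto'")

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "base_channels": self.base_channels,
            "encoder_name": self.encoder_name,
            "loss": self.loss,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
            "threshold": self.threshold,
            "keep_empty_slices": self.keep_empty_slices,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass(frozen=True)
class SplitPlan:
    """Subject-level train/test assignment per fold.

    ``folds`` is a tuple of (test_ids, train_ids) tuples.  Test subjects
    never contribute training slices, and the test sets partition the
    cohort.
    """

    folds: tuple[tuple[tuple, tuple], ...]
    scheme: str

    def __post_init__(self) -> None:
        seen: list = []
        for test_ids, train_ids in self.folds:
            if set(test_ids) & set(train_ids):
                raise ValueError("a subject appears in both train and test of one fold")
            seen.extend(test_ids)
        if len(seen) != len(set(seen)):
            raise ValueError("test sets must be disjoint across folds")

    @classmethod
    def leave_one_out(cls, subject_ids: list) -> "SplitPlan":
        ids = list(subject_ids)
        folds = tuple(
            ((sid,), tuple(s for s in ids if s != sid)) for sid in ids
        )
        return cls(folds=folds, scheme="leave-one-out")

    @classmethod
    def k_fold(cls, subject_ids: list, k: int, seed: int = 0) -> "SplitPlan":
        ids = list(subject_ids)
        if len(ids) < k:
            raise ValueError(f"need at least {k} subjects for {k}-fold CV, got {len(ids)}")
        order = np.random.default_rng(seed).permutation(len(ids))
        chunks = np.array_split(order, k)
        folds = []
        for chunk in chunks:
            test = tuple(ids[i] for i in chunk)
            train = tuple(s for s in ids if s not in test)
            folds.append((test, train))
        return cls(folds=tuple(folds), scheme="k-fold")


def build_model(config: ModelConfig, input_size: tuple[int, int] | None = None) -> UNet2D:
    """Construct the segmentation network from a config.

    The network maps a 1-channel H×W slice to an H×W per-pixel spleen
    probability map, with ``config.depth`` encoder stages, matching
    decoder stages and skip connections between matched stages.  If
    ``input_size`` is given, divisibility by 2**depth is validated
    immediately rather than at first forward pass.
    """
    if input_size is not None:
        div = 2 ** config.depth
        if input_size[0] % div or input_size[1] % div:
            raise ValueError(
                f"input size {input_size} not divisible by 2^depth = {div}"
            )
    return UNet2D(
        depth=config.depth,
        base_channels=config.base_channels,
        in_channels=1,
        seed=config.seed,
        residual_encoder=(config.encoder_name == "resnet34-style"),
    )


# ---------------------------------------------------------------------------
# dataset assembly


def build_training_set(
    subjects: list[tuple[object, ScanVolume, MaskVolume]],
    preproc: PreprocConfig,
    config: ModelConfig,
    augment: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess and (optionally) augment subjects into slice arrays.

    Returns float32 images (N, H, W) and uint8 masks (N, H, W).  With
    augmentation and the default ±5° angles the slice count triples.
    Slices without spleen are kept by default — the full-scan evaluation
    requires the model to have seen spleen-free anatomy.
    """
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for _, scan, gt in subjects:
        pscan, pmask = preprocess_scan(scan, preproc, mask=gt)
        for i in range(pscan.n_slices):
            if not config.keep_empty_slices and pmask.voxels[i].sum() == 0:
                continue
            pairs.append((pscan.voxels[i], pmask.voxels[i]))
    if augment:
        pairs = augment_rotations(pairs, preproc.rotation_degrees)
    images = np.stack([p[0] for p in pairs]).astype(np.float32)
    masks = np.stack([p[1] for p in pairs]).astype(np.uint8)
    return images, masks


# ---------------------------------------------------------------------------
# training


def train(
    model: UNet2D,
    train_slices: tuple[np.ndarray, np.ndarray],
    config: ModelConfig,
) -> list[dict]:
    """Train in place; returns the per-epoch history.

    History entries carry the mean batch loss and the Dice on a fixed
    held-in subsample (up to 32 slices).  A non-finite loss aborts with
    :class:`TrainingDivergedError`.  Zero epochs return the initialized
    model untouched with an empty history.  Deterministic per
    ``config.seed``.
    """
    images, masks = train_slices
    if images.ndim != 3 or images.shape != masks.shape:
        raise ValueError("train slices must be aligned (N, H, W) arrays")
    lr = config.learning_rate
    if lr == "auto":
        raise ValueError("learning_rate 'auto' must be resolved via tune_learning_rate first")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model, lr=float(lr))
    n = images.shape[0]
    heldin = np.arange(min(32, n))
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x = images[idx][:, None]
            y = masks[idx][:, None].astype(np.float32)
            logits = model.forward(x)
            loss, dldz = segmentation_loss(logits, y, kind=config.loss)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            model.backward(dldz)
            opt.step()
            losses.append(loss)
        probs = _predict_slices(model, images[heldin], config)
        d = dice(
            MaskVolume(masks[heldin]),
            MaskVolume((probs >= config.threshold).astype(np.uint8)),
        )
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "train_dice": float(d)})
    return history


def _predict_slices(model: UNet2D, images: np.ndarray, config: ModelConfig,
                    batch: int = 16) -> np.ndarray:
    probs = np.empty_like(images, dtype=np.float32)
    for start in range(0, images.shape[0], batch):
        x = images[start:start + batch][:, None]
        probs[start:start + batch] = model.predict_proba(x)[:, 0]
    return probs


def predict_volume(
    model: UNet2D,
    scan: ScanVolume,
    preproc: PreprocConfig,
    config: ModelConfig,
) -> MaskVolume:
    """Segment a scan slice by slice into a raw prediction mask.

    The scan is preprocessed exactly as in training (body-restricted
    normalization, bottom-right crop); probability maps are thresholded
    at ``config.threshold`` and the cropped predictions are pasted back
    into a full-size mask aligned with the input scan.
    """
    pscan, _ = preprocess_scan(scan, preproc)
    probs = _predict_slices(model, pscan.voxels, config)
    binary = (probs >= config.threshold).astype(np.uint8)
    full = np.zeros(scan.shape, dtype=np.uint8)
    size = preproc.crop_size
    full[:, scan.shape[1] - size:, scan.shape[2] - size:] = binary
    return MaskVolume(full, role="MP_raw")


# ---------------------------------------------------------------------------
# cross-validation harnesses


def tune_learning_rate(
    train_subjects: list[tuple[object, ScanVolume, MaskVolume]],
    candidate_lrs: list[float],
    config: ModelConfig,
    preproc: PreprocConfig,
    k: int = 5,
    seed: int = 0,
) -> float:
    """Pick the learning rate maximizing mean validation Dice in k-fold CV.

    Folds are assigned by subject, never by slice.  A candidate whose
    training diverges (non-finite loss) scores 0 on that fold.  Ties and
    the single-candidate case resolve to the smallest candidate.
    Deterministic per ``seed``.
    """
    if not candidate_lrs:
        raise ValueError("candidate_lrs must be nonempty")
    ids = [sid for sid, _, _ in train_subjects]
    plan = SplitPlan.k_fold(ids, k=k, seed=seed)
    by_id = {sid: (sid, scan, gt) for sid, scan, gt in train_subjects}
    scores: dict[float, float] = {}
    for lr in sorted(candidate_lrs):
        fold_dice = []
        for test_ids, train_ids in plan.folds:
            cfg = replace(config, learning_rate=float(lr))
            model = build_model(cfg)
            xtr, ytr = build_training_set([by_id[s] for s in train_ids], preproc, cfg)
            try:
                train(model, (xtr, ytr), cfg)
            except TrainingDivergedError:
                fold_dice.append(0.0)
                continue
            ds = []
            for sid in test_ids:
                _, scan, gt = by_id[sid]
                pscan, pmask = preprocess_scan(scan, preproc, mask=gt)
                probs = _predict_slices(model, pscan.voxels, cfg)
                pred = MaskVolume((probs >= cfg.threshold).astype(np.uint8))
                ds.append(dice(pmask, pred))
            fold_dice.append(float(np.mean(ds)))
        scores[float(lr)] = float(np.mean(fold_dice))
    best = max(sorted(scores), key=lambda lr: scores[lr])
    return best


def run_loocv(
    cohort: list[tuple[object, ScanVolume, MaskVolume]],
    config: ModelConfig,
    preproc: PreprocConfig,
) -> tuple[list[tuple[object, MaskVolume]], SplitPlan]:
    """Leave-one-out cross-validation over subjects.

    One model is trained per held-out subject on all remaining subjects'
    augmented slices; the held-out subject's full scan (including its
    spleen-free slices) is then predicted by that model.  Returns the raw
    predictions and the split plan for leakage auditing.
    """
    if len(cohort) < 2:
        raise ValueError("leave-one-out needs at least 2 subjects")
    ids = [sid for sid, _, _ in cohort]
    plan = SplitPlan.leave_one_out(ids)
    by_id = {sid: (sid, scan, gt) for sid, scan, gt in cohort}
    predictions: list[tuple[object, MaskVolume]] = []
    for (test_ids, train_ids) in plan.folds:
        model = build_model(config)
        xtr, ytr = build_training_set([by_id[s] for s in train_ids], preproc, config)
        train(model, (xtr, ytr), config)
        sid = test_ids[0]
        _, scan, _ = by_id[sid]
        predictions.append((sid, predict_volume(model, scan, preproc, config)))
    return predictions, plan


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: UNet2D, config: ModelConfig, path: str | os.PathLike) -> None:
    """Save weights (npz) plus the ModelConfig (json sidecar) for reproducibility."""
    np.savez(path, **model.state_arrays())
    with open(str(path) + ".json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)


def load_checkpoint(path: str | os.PathLike) -> tuple[UNet2D, ModelConfig]:
    with open(str(path) + ".json") as fh:
        config = ModelConfig.from_dict(json.load(fh))
    model = build_model(config)
    with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as data:
        model.load_state_arrays(dict(data))
    return model, config
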