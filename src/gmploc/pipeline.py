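"""End-to-end orchestration: cross-validation with fold-restricted
rebalancing and the classifier ablation matrix.

The workflow per fold is: fit the feature scaler on the training
split; optionally rebalance the training split by training one
minority-class GAN per under-represented label; train each requested
classifier arm (FM only, Deep only, or both) on the (augmented)
training split; evaluate on the untouched test split with the five
multi-label metrics.

Rebalancing and scaling always derive from the training split alone,
so no information about a fold's test samples leaks into training —
synthetic samples are re-generated inside every fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import MultiLabelDataset
from .metrics import MetricsReport, PredictionSet, evaluate_all
from .mldeepfm import ClassifierConfig, LossConfig, decide_labels, train_mldeepfm
from .pssm import FeatureScaler
from .smgan import GANTrainConfig, plan_rebalance, rebalance_dataset

__all__ = [
    "Arm", "ExperimentConfig", "CVResult", "kfold_split",
    "run_cross_validation", "dataset_report", "DEFAULT_ARMS",
]

logger = logging.getLogger(__name__)

CLASSIFIERS = ("ML-FM", "ML-Deep", "ML-DeepFM")


@dataclass(frozen=True)
class Arm:
    classifier: str          # one of CLASSIFIERS
    smgan: bool              # rebalance the training fold first?

    def __post_init__(self):
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")

    @property
    def name(self) -> str:
        return self.classifier + ("+SMGAN" if self.smgan else "")


#: The full 3 x 2 ablation matrix.
DEFAULT_ARMS = tuple(Arm(c, g) for c in CLASSIFIERS for g in (True, False))


@dataclass
class ExperimentConfig:
    folds: int = 10
    arms: tuple[Arm, ...] = DEFAULT_ARMS
    gan: GANTrainConfig = field(default_factory=GANTrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    k_lat: int = 8
    hidden: tuple[int, ...] = (256, 128, 64, 32)
    dropout: float = 0.5
    epochs: int = 1000
    batch_size: int = 512
    learning_rate: float = 1e-4
    rebalance_policy: str = "match_majority"
    rebalance_ratio: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.arms:
            raise ValueError("at least one arm is required")


@dataclass
class CVResult:
    per_fold: dict[str, list[MetricsReport]]   # arm name -> fold reports
    aggregate: dict[str, dict[str, tuple[float, float]]]  # arm -> metric -> (mean, sd)
    fold_manifest: list[list[int]]             # test indices per fold
    config: ExperimentConfig = None


def kfold_split(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Random disjoint folds covering range(n); sizes differ by at
    most one (larger folds first)."""
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def _classifier_config(arm: Arm, cfg: ExperimentConfig, n_features: int,
                       n_labels: int, seed: int) -> ClassifierConfig:
    return ClassifierConfig(
        n_features=n_features, n_labels=n_labels, k_lat=cfg.k_lat,
        hidden=cfg.hidden, dropout=cfg.dropout,
        include_fm=arm.classifier in ("ML-FM", "ML-DeepFM"),
        include_deep=arm.classifier in ("ML-Deep", "ML-DeepFM"),
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, seed=seed, loss=cfg.loss)


def run_cross_validation(dataset: MultiLabelDataset,
                         cfg: ExperimentConfig) -> CVResult:
    n = dataset.n_samples
    folds = kfold_split(n, cfg.folds, cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    per_fold: dict[str, list[MetricsReport]] = {a.name: [] for a in cfg.arms}
    needs_gan = any(a.smgan for a in cfg.arms)
    all_idx = np.arange(n)
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train_ds = dataset.subset(train_idx)
        test_ds = dataset.subset(test_idx)
        scaler = FeatureScaler().fit(train_ds.flat_features())
        fold_gan_seed = int(rng.integers(0, 2 ** 31 - 1))
        augmented = None
        if needs_gan:
            plan = plan_rebalance(train_ds.labels, policy=cfg.rebalance_policy,
                                  ratio=cfg.rebalance_ratio)
            missing = np.flatnonzero(plan.real_counts == 0)
            if missing.size:
                logger.warning(
                    "fold %d: training split lacks class(es) %s; skipped by "
                    "the rebalancer", f,
                    [dataset.label_names[k] for k in missing])
                plan.synth_counts[missing] = 0
            gan_cfg = GANTrainConfig(
                latent_dim=cfg.gan.latent_dim, lambda_reg=cfg.gan.lambda_reg,
                epochs=cfg.gan.epochs, batch_size=cfg.gan.batch_size,
                learning_rate=cfg.gan.learning_rate,
                epsilon_dist=cfg.gan.epsilon_dist, seed=fold_gan_seed)
            augmented = rebalance_dataset(train_ds, plan, gan_cfg, scaler=scaler)
        x_test = scaler.transform(test_ds.flat_features())
        for arm in cfg.arms:
            source = augmented if arm.smgan else train_ds
            x_train = scaler.transform(source.flat_features())
            arm_seed = int(rng.integers(0, 2 ** 31 - 1))
            ccfg = _classifier_config(arm, cfg, x_train.shape[1],
                                      dataset.n_labels, arm_seed)
            model, _ = train_mldeepfm(x_train, source.labels, ccfg)
            scores = model.scores(x_test)
            preds = decide_labels(scores, cfg.loss.y0)
            pred_set = PredictionSet(scores=scores, predictions=preds,
                                     truth=test_ds.labels)
            per_fold[arm.name].append(evaluate_all(pred_set, fold=f,
                                                   arm=arm.name))
    aggregate = {}
    for name, reports in per_fold.items():
        agg = {}
        for m in ("hl", "oe", "co", "rl", "ap"):
            vals = np.array([getattr(r, m) for r in reports], dtype=float)
            agg[m] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
        aggregate[name] = agg
    return CVResult(per_fold=per_fold, aggregate=aggregate,
                    fold_manifest=[idx.tolist() for idx in folds], config=cfg)


def dataset_report(dataset: MultiLabelDataset) -> dict:
    """Imbalance summary: per-class counts and proportions, the
    label-cardinality histogram, and the majority/minority ratio."""
    if dataset.n_samples == 0:
        raise ValueError("empty dataset")
    counts = dataset.labels.sum(axis=0)
    card = dataset.labels.sum(axis=1)
    histogram = {
        "1": int((card == 1).sum()),
        "2": int((card == 2).sum()),
        "3": int((card == 3).sum()),
        "4+": int((card >= 4).sum()),
    }
    nonzero = counts[counts > 0]
    return {
        "n_samples": dataset.n_samples,
        "n_labels": dataset.n_labels,
        "class_counts": {name: int(c) for name, c
                         in zip(dataset.label_names, counts)},
        "class_proportions": {name: float(c) / dataset.n_samples
                              for name, c in zip(dataset.label_names, counts)},
        "cardinality_histogram": histogram,
        "max_min_ratio": (float(nonzero.max()) / float(nonzero.min())
                          if nonzero.size else float("nan")),
    }
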