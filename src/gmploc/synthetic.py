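"""Synthetic imbalanced multi-label datasets and on-disk PSSM fixtures.

The generator draws class-conditional isotropic Gaussians: each base
class k contributes ``n_per_class[k]`` samples centred at
``class_means[k]`` with standard deviation ``noise_sd``, labelled k
plus each extra label j independently with probability
``cooccurrence[k, j]``. This is deliberately the simplest structure
under which the SM-GAN mean-matching regularizer has a known target;
it does not attempt to mimic real PSSM score distributions.

Feature shapes are free: the pipeline default is 20x20, while small
toy shapes keep GAN and classifier tests fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import MultiLabelDataset
from .pssm import AA_ORDER, ProteinRecord, PSSMMatrix, pssm_to_ascii

__all__ = [
    "SyntheticConfig", "generate_multilabel_dataset", "imbalance_profile",
    "write_pssm_fixture", "random_pssm", "imbalanced_three_class_config",
]


@dataclass
class SyntheticConfig:
    n_per_class: tuple[int, ...]             # per-base-class sample counts
    class_means: np.ndarray | None = None    # (K, *feature_shape)
    feature_shape: tuple[int, ...] = (2,)
    noise_sd: float = 1.0
    cooccurrence: np.ndarray | None = None   # (K, K), diagonal 1
    separation: float = 3.0                  # used when class_means is None
    seed: int = 0
    class_names: list[str] = field(default=None)

    def __post_init__(self):
        self.n_per_class = tuple(int(n) for n in self.n_per_class)
        if any(n < 0 for n in self.n_per_class):
            raise ValueError("n_per_class entries must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        K = len(self.n_per_class)
        if self.class_means is None:
            # deterministic well-separated means: cycle through axes
            dim = int(np.prod(self.feature_shape))
            means = np.zeros((K, dim))
            for k in range(K):
                means[k, k % dim] = self.separation * (1 + k // dim)
            self.class_means = means.reshape((K,) + tuple(self.feature_shape))
        else:
            self.class_means = np.asarray(self.class_means, dtype=float)
            self.feature_shape = self.class_means.shape[1:]
        if self.class_means.shape[0] != K:
            raise ValueError("class_means must provide one mean per class")
        if self.cooccurrence is None:
            self.cooccurrence = np.eye(K)
        else:
            self.cooccurrence = np.asarray(self.cooccurrence, dtype=float)
            if self.cooccurrence.shape != (K, K):
                raise ValueError("cooccurrence must be K x K")
            if ((self.cooccurrence < 0) | (self.cooccurrence > 1)).any():
                raise ValueError("cooccurrence entries must be probabilities")
            if not np.allclose(np.diag(self.cooccurrence), 1.0):
                raise ValueError("cooccurrence diagonal must be 1")
        if self.class_names is None:
            self.class_names = [f"class_{k}" for k in range(K)]

    @property
    def n_classes(self) -> int:
        return len(self.n_per_class)


def imbalanced_three_class_config(seed: int = 0) -> SyntheticConfig:
    """The package's reference imbalance study: three classes with
    500/50/20 samples in 16-D, unit noise, and the two minority
    classes co-occurring with probability 0.2.

    Class means are sign patterns +-a over the first three feature
    dimensions (a = 1.8, about 5 sigma between any two classes), so
    class identity is carried by the joint sign structure of a few
    coordinates rather than a single marginal. The minority classes
    are populous enough to pin down in the 16-D feature space from
    hundreds of samples but not from tens — the regime in which class
    imbalance actually damages minority ranking.
    """
    a = 1.8
    means = np.zeros((3, 16))
    means[0, :3] = [a, a, a]
    means[1, :3] = [a, -a, -a]
    means[2, :3] = [-a, a, -a]
    co = np.eye(3)
    co[1, 2] = co[2, 1] = 0.2
    return SyntheticConfig(
        n_per_class=(500, 50, 20),
        class_means=means,
        noise_sd=1.0,
        cooccurrence=co,
        seed=seed,
    )


def generate_multilabel_dataset(cfg: SyntheticConfig) -> MultiLabelDataset:
    if sum(cfg.n_per_class) == 0:
        raise ValueError("at least one class must have a positive sample count")
    rng = np.random.default_rng(cfg.seed)
    K = cfg.n_classes
    feats, labels, ids = [], [], []
    for k, n_k in enumerate(cfg.n_per_class):
        if n_k == 0:
            continue
        x = cfg.class_means[k][None] + rng.normal(
            0.0, cfg.noise_sd, size=(n_k,) + tuple(cfg.feature_shape))
        y = np.zeros((n_k, K), dtype=int)
        y[:, k] = 1
        for j in range(K):
            if j == k:
                continue
            p = cfg.cooccurrence[k, j]
            if p > 0:
                y[:, j] = rng.random(n_k) < p
        feats.append(x)
        labels.append(y)
        ids += [f"{cfg.class_names[k]}_{i}" for i in range(n_k)]
    manifest = {
        "n_per_class": list(cfg.n_per_class),
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
        "feature_shape": list(cfg.feature_shape),
        "cooccurrence": np.asarray(cfg.cooccurrence).tolist(),
        "class_means": np.asarray(cfg.class_means).tolist(),
    }
    return MultiLabelDataset(
        features=np.concatenate(feats),
        labels=np.concatenate(labels),
        ids=ids,
        label_names=list(cfg.class_names),
        manifest=manifest,
    )


def imbalance_profile(dataset: MultiLabelDataset) -> np.ndarray:
    """Per-class proportion of samples bearing each label. For
    multi-label data the proportions can sum to more than 1."""
    if dataset.n_samples == 0:
        raise ValueError("empty dataset")
    return dataset.labels.sum(axis=0) / dataset.n_samples


def random_pssm(protein_id: str, length: int, rng: np.random.Generator,
                alphabet: str = AA_ORDER) -> PSSMMatrix:
    """Random integer log-odds PSSM for round-trip and parser tests."""
    residues = "".join(rng.choice(list(alphabet), size=length))
    scores = rng.integers(-16, 17, size=(length, 20)).astype(float)
    return PSSMMatrix(protein_id=protein_id, residues=residues, scores=scores)


def write_pssm_fixture(record: ProteinRecord, scores: np.ndarray,
                       path: str | Path) -> Path:
    """Write a PSI-BLAST-dialect ASCII PSSM that parse_pssm_ascii
    round-trips exactly on (residues, scores)."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (record.length, 20):
        raise ValueError(
            f"scores shape {scores.shape} does not match protein length "
            f"{record.length} x 20")
    pssm = PSSMMatrix(protein_id=record.id, residues=record.sequence,
                      scores=scores)
    path = Path(path)
    path.write_text(pssm_to_ascii(pssm))
    return path
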