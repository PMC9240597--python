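"""Distance-regularized GAN for synthesizing minority-class samples.

The generator maps latent noise to feature matrices; the discriminator
scores the probability that a sample is real. On top of the standard
non-saturating adversarial game, both objectives carry a log-distance
term d = ||G(z) - x_bar||_2 between each generated sample and the mean
x_bar of the real minority pool:

* discriminator value (maximized):
  E[log D(x)] + E[log(1 - D(G(z)))] + E[log d]
* generator loss (minimized):
  E[-log D(G(z))] + lambda * E[log d]

The distance term does not involve discriminator parameters, so the
discriminator update is the usual one; the generator feels an extra
pull of strength lambda toward the real mean. Distances are floored
at a small epsilon before the log so a generated sample coinciding
with the mean cannot produce -inf.

One unconditional GAN is trained per minority class on the samples
bearing that class's label; synthesized samples are appended carrying
that single label and a synthetic flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .dataset import MultiLabelDataset
from .pssm import FeatureScaler

__all__ = [
    "GANTrainConfig", "ClassBalancePlan", "GeneratorState",
    "distance_term", "discriminator_objective", "generator_objective",
    "build_generator", "build_discriminator", "train_smgan", "synthesize",
    "plan_rebalance", "rebalance_dataset",
]

logger = logging.getLogger(__name__)

_P_CLAMP = 1e-6


@dataclass
class GANTrainConfig:
    latent_dim: int = 64
    lambda_reg: float = 0.1
    epochs: int = 1000
    batch_size: int = 512          # clipped to the pool size
    learning_rate: float = 1e-4
    epsilon_dist: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be nonnegative")
        if self.epsilon_dist <= 0:
            raise ValueError("epsilon_dist must be positive")


@dataclass
class ClassBalancePlan:
    real_counts: np.ndarray        # (K,) samples bearing each label
    synth_counts: np.ndarray       # (K,) samples to synthesize per label
    policy: str

    def __post_init__(self):
        self.real_counts = np.asarray(self.real_counts, dtype=int)
        self.synth_counts = np.asarray(self.synth_counts, dtype=int)
        if (self.synth_counts < 0).any():
            raise ValueError("synthesis counts must be nonnegative")


@dataclass
class GeneratorState:
    generator: nn.Sequential
    feature_shape: tuple[int, ...]
    config: GANTrainConfig
    loss_trace: list[tuple[float, float]] = field(default_factory=list)
    scaler: FeatureScaler | None = None

    def state_arrays(self) -> list[np.ndarray]:
        return self.generator.state()


def distance_term(fake_batch: np.ndarray, real_mean: np.ndarray,
                  epsilon: float) -> np.ndarray:
    """Per-sample Euclidean distance to the real mean, floored at epsilon."""
    fake_batch = np.asarray(fake_batch, dtype=float)
    real_mean = np.asarray(real_mean, dtype=float)
    if fake_batch.shape[1:] != real_mean.shape:
        raise ValueError(
            f"shape mismatch: batch {fake_batch.shape[1:]} vs mean {real_mean.shape}")
    diff = fake_batch.reshape(fake_batch.shape[0], -1) - real_mean.reshape(-1)
    d = np.sqrt((diff ** 2).sum(axis=1))
    return np.maximum(d, epsilon)


def discriminator_objective(d_real: np.ndarray, d_fake: np.ndarray,
                            dist: np.ndarray) -> float:
    """Value the discriminator maximizes (training minimizes its negation)."""
    p_r = np.clip(np.asarray(d_real, dtype=float), _P_CLAMP, 1 - _P_CLAMP)
    p_f = np.clip(np.asarray(d_fake, dtype=float), _P_CLAMP, 1 - _P_CLAMP)
    return float(np.log(p_r).mean() + np.log1p(-p_f).mean()
                 + np.log(np.asarray(dist, dtype=float)).mean())


def generator_objective(d_fake: np.ndarray, dist: np.ndarray,
                        lambda_reg: float) -> float:
    """Loss the generator minimizes."""
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be nonnegative")
    p_f = np.clip(np.asarray(d_fake, dtype=float), _P_CLAMP, 1 - _P_CLAMP)
    return float((-np.log(p_f)).mean()
                 + lambda_reg * np.log(np.asarray(dist, dtype=float)).mean())


def build_generator(feature_shape: tuple[int, ...], latent_dim: int,
                    rng: np.random.Generator) -> nn.Sequential:
    """Dense layer feeding three transposed convolutions for 20x20
    features; a dense stack for toy shapes."""
    if tuple(feature_shape) == (20, 20):
        return nn.Sequential(
            nn.Dense(latent_dim, 32 * 5 * 5, rng), nn.ReLU(),
            nn.Reshape((32, 5, 5)),
            nn.ConvTranspose2d(32, 16, k=4, stride=2, pad=1, rng=rng), nn.ReLU(),
            nn.ConvTranspose2d(16, 8, k=4, stride=2, pad=1, rng=rng), nn.ReLU(),
            nn.ConvTranspose2d(8, 1, k=3, stride=1, pad=1, rng=rng),
        )
    dim = int(np.prod(feature_shape))
    return nn.Sequential(
        nn.Dense(latent_dim, 64, rng), nn.ReLU(),
        nn.Dense(64, 64, rng), nn.ReLU(),
        nn.Dense(64, dim, rng),
    )


def build_discriminator(feature_shape: tuple[int, ...],
                        rng: np.random.Generator) -> nn.Sequential:
    """Two convolutions feeding a dense sigmoid head for 20x20 features;
    a dense stack for toy shapes."""
    if tuple(feature_shape) == (20, 20):
        return nn.Sequential(
            nn.Conv2d(1, 8, k=4, stride=2, pad=1, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(8, 16, k=4, stride=2, pad=1, rng=rng), nn.LeakyReLU(),
            nn.Flatten(),
            nn.Dense(16 * 5 * 5, 1, rng), nn.Sigmoid(),
        )
    dim = int(np.prod(feature_shape))
    return nn.Sequential(
        nn.Dense(dim, 64, rng), nn.LeakyReLU(),
        nn.Dense(64, 64, rng), nn.LeakyReLU(),
        nn.Dense(64, 1, rng), nn.Sigmoid(),
    )


def _to_net_input(x: np.ndarray, feature_shape: tuple[int, ...]) -> np.ndarray:
    if tuple(feature_shape) == (20, 20):
        return x.reshape(-1, 1, 20, 20)
    return x.reshape(-1, int(np.prod(feature_shape)))


def _from_net_output(x: np.ndarray, feature_shape: tuple[int, ...]) -> np.ndarray:
    return x.reshape((-1,) + tuple(feature_shape))


def train_smgan(samples: np.ndarray, config: GANTrainConfig,
                scaler: FeatureScaler | None = None) -> GeneratorState:
    """Alternating 1:1 discriminator/generator Adam updates.

    ``samples`` is (N, *feature_shape) in the (scaled) space the GAN
    models; an attached scaler makes synthesize() return feature units.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    if n < 2:
        raise ValueError(f"SM-GAN needs at least 2 samples, got {n}")
    feature_shape = samples.shape[1:]
    rng = np.random.default_rng(config.seed)
    gen = build_generator(feature_shape, config.latent_dim, rng)
    disc = build_discriminator(feature_shape, rng)
    opt_g = nn.Adam(gen.params(), gen.grads(), lr=config.learning_rate)
    opt_d = nn.Adam(disc.params(), disc.grads(), lr=config.learning_rate)
    real_mean = samples.mean(axis=0)
    batch = min(config.batch_size, n)
    eps = config.epsilon_dist
    trace: list[tuple[float, float]] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        d_vals, g_vals = [], []
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            real = _to_net_input(samples[idx], feature_shape)
            b = real.shape[0]

            # --- discriminator step (distance term has no D parameters)
            z = rng.standard_normal((b, config.latent_dim))
            fake = gen.forward(z, train=True)
            both = np.concatenate([real, fake])
            p = np.clip(disc.forward(both, train=True)[:, 0], _P_CLAMP, 1 - _P_CLAMP)
            p_r, p_f = p[:b], p[b:]
            dist = distance_term(_from_net_output(fake, feature_shape),
                                 real_mean, eps)
            d_vals.append(discriminator_objective(p_r, p_f, dist))
            grad = np.empty((2 * b, 1))
            grad[:b, 0] = -1.0 / (b * p_r)          # minimize -log p_real
            grad[b:, 0] = 1.0 / (b * (1.0 - p_f))   # minimize -log(1 - p_fake)
            disc.backward(grad)
            opt_d.step()

            # --- generator step
            z = rng.standard_normal((b, config.latent_dim))
            fake = gen.forward(z, train=True)
            p_f = np.clip(disc.forward(fake, train=True)[:, 0], _P_CLAMP, 1 - _P_CLAMP)
            fake_flat = fake.reshape(b, -1)
            diff = fake_flat - real_mean.reshape(-1)
            d_raw = np.sqrt((diff ** 2).sum(axis=1))
            dist = np.maximum(d_raw, eps)
            g_vals.append(generator_objective(p_f, dist, config.lambda_reg))
            grad_p = np.empty((b, 1))
            grad_p[:, 0] = -1.0 / (b * p_f)
            grad_fake = disc.backward(grad_p)       # D frozen: grads unused
            # lambda * d/dfake of mean log ||fake - mean||; flat below the floor
            active = (d_raw > eps).astype(float)
            reg = (config.lambda_reg / b) * (active / np.maximum(d_raw, eps) ** 2)[:, None] * diff
            grad_fake = grad_fake + reg.reshape(fake.shape)
            gen.backward(grad_fake)
            opt_g.step()
        trace.append((float(np.mean(d_vals)), float(np.mean(g_vals))))
    return GeneratorState(generator=gen, feature_shape=tuple(feature_shape),
                          config=config, loss_trace=trace, scaler=scaler)


def synthesize(state: GeneratorState, n: int, seed: int) -> np.ndarray:
    """Draw n samples from the trained generator; inverse-scaled to
    feature units when a scaler is attached."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    shape = state.feature_shape
    if n == 0:
        return np.empty((0,) + shape)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, state.config.latent_dim))
    out = _from_net_output(state.generator.forward(z), shape)
    if state.scaler is not None:
        flat = state.scaler.inverse_transform(out.reshape(n, -1))
        out = flat.reshape((n,) + shape)
    return out


def plan_rebalance(label_matrix: np.ndarray, policy: str = "match_majority",
                   ratio: float | None = None) -> ClassBalancePlan:
    """Per-class synthesis counts from an N x K binary label matrix."""
    labels = np.asarray(label_matrix, dtype=int)
    if labels.ndim != 2 or labels.shape[0] == 0:
        raise ValueError("label matrix must be a non-empty N x K array")
    if (labels.sum(axis=1) == 0).any():
        raise ValueError("every sample must carry at least one label")
    counts = labels.sum(axis=0)
    majority = int(counts.max())
    if policy == "match_majority":
        synth = majority - counts
    elif policy == "ratio":
        if ratio is None or ratio <= 0:
            raise ValueError("ratio policy requires a positive ratio")
        target = int(np.ceil(ratio * majority))
        synth = np.maximum(0, target - counts)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return ClassBalancePlan(real_counts=counts, synth_counts=synth,
                            policy=policy)


def rebalance_dataset(dataset: MultiLabelDataset, plan: ClassBalancePlan,
                      config: GANTrainConfig,
                      scaler: FeatureScaler | None = None,
                      jitter_sd: float = 0.05) -> MultiLabelDataset:
    """Train one SM-GAN per under-represented class and append its
    synthetic samples (single-label, synthetic=True). Real samples are
    untouched. A class with fewer than 2 real samples falls back to
    duplicate-with-jitter."""
    if plan.synth_counts.shape[0] != dataset.n_labels:
        raise ValueError("plan does not match the dataset's label count")
    out = dataset
    rng = np.random.default_rng(config.seed)
    for k in range(dataset.n_labels):
        n_new = int(plan.synth_counts[k])
        if n_new == 0:
            continue
        pool_idx = np.flatnonzero(dataset.labels[:, k] == 1)
        name = dataset.label_names[k]
        flat = dataset.flat_features()[pool_idx]
        if scaler is not None:
            flat = scaler.transform(flat)
        pool = flat.reshape((len(pool_idx),) + dataset.feature_shape)
        class_seed = int(rng.integers(0, 2 ** 31 - 1))
        if len(pool_idx) < 2:
            logger.warning(
                "class %r has %d real sample(s); duplicating with jitter "
                "instead of GAN training", name, len(pool_idx))
            jrng = np.random.default_rng(class_seed)
            base = pool[jrng.integers(0, len(pool_idx), size=n_new)]
            synth_flat = base.reshape(n_new, -1) + jrng.normal(
                0.0, jitter_sd, size=(n_new, int(np.prod(dataset.feature_shape))))
            if scaler is not None:
                synth_flat = scaler.inverse_transform(synth_flat)
            synth = synth_flat.reshape((n_new,) + dataset.feature_shape)
        else:
            cls_cfg = GANTrainConfig(
                latent_dim=config.latent_dim, lambda_reg=config.lambda_reg,
                epochs=config.epochs, batch_size=config.batch_size,
                learning_rate=config.learning_rate,
                epsilon_dist=config.epsilon_dist, seed=class_seed)
            state = train_smgan(pool, cls_cfg, scaler=scaler)
            synth = synthesize(state, n_new, seed=class_seed + 1)
        labels_new = np.zeros((n_new, dataset.n_labels), dtype=int)
        labels_new[:, k] = 1
        addition = MultiLabelDataset(
            features=synth, labels=labels_new,
            ids=[f"syn_{name}_{i}" for i in range(n_new)],
            label_names=list(dataset.label_names),
            synthetic=np.ones(n_new, dtype=bool))
        out = out.concat(addition)
    return out
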