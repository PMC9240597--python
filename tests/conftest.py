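import numpy as np
import pytest

from gmploc.dataset import MultiLabelDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_pssm_text():
    """Minimal PSI-BLAST dialect: 3 residues, known integer scores."""
    rows = [
        "",
        "Last position-specific scoring matrix computed, weighted observed percentages",
        "            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V",
        "    1 A  " + " ".join(f"{v:4d}" for v in range(2, 22)),
        "    2 C  " + " ".join(f"{v:4d}" for v in range(-1, 19)),
        "    3 A  " + " ".join(f"{v:4d}" for v in range(4, 24)),
        "",
        "                      K         Lambda",
    ]
    return "\n".join(rows) + "\n"


def make_toy_dataset(n0=30, n1=10, k=2, dim=2, seed=0, sep=3.0):
    """Two-class single-label Gaussian toy with configurable imbalance."""
    rng = np.random.default_rng(seed)
    means = np.zeros((k, dim))
    for j in range(k):
        means[j, j % dim] = sep * (1 + j // dim)
    counts = [n0, n1] + [n1] * (k - 2)
    feats, labels, ids = [], [], []
    for j, n in enumerate(counts[:k]):
        feats.append(means[j] + rng.normal(0, 1.0, size=(n, dim)))
        y = np.zeros((n, k), dtype=int)
        y[:, j] = 1
        labels.append(y)
        ids += [f"c{j}_{i}" for i in range(n)]
    return MultiLabelDataset(
        features=np.concatenate(feats), labels=np.concatenate(labels),
        ids=ids, label_names=[f"c{j}" for j in range(k)])


@pytest.fixture
def toy_dataset():
    return make_toy_dataset()
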