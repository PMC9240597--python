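"""Aligned container for multi-label protein feature data.

Features are stored per sample with an arbitrary trailing shape (the
pipeline default is a 20x20 PSSM-composition matrix; tests use small
toy shapes), alongside a binary N x K label matrix, sample ids, and a
flag marking GAN-synthesized rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["MultiLabelDataset"]


@dataclass
class MultiLabelDataset:
    features: np.ndarray          # (N, *feature_shape), finite
    labels: np.ndarray            # (N, K) in {0, 1}; every row has >= 1 label
    ids: list[str]
    label_names: list[str]
    synthetic: np.ndarray = None  # (N,) bool; True for GAN-made samples
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.features.shape[0]
        if self.labels.shape[0] != n or len(self.ids) != n:
            raise ValueError("features, labels and ids must align on N")
        if self.labels.ndim != 2 or self.labels.shape[1] != len(self.label_names):
            raise ValueError("labels must be N x K with K == len(label_names)")
        if n and not np.isfinite(self.features).all():
            raise ValueError("features contain non-finite values")
        if n and (self.labels.sum(axis=1) == 0).any():
            raise ValueError("every sample must carry at least one label")
        if self.synthetic is None:
            self.synthetic = np.zeros(n, dtype=bool)
        else:
            self.synthetic = np.asarray(self.synthetic, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_labels(self) -> int:
        return self.labels.shape[1]

    @property
    def feature_shape(self) -> tuple[int, ...]:
        return self.features.shape[1:]

    def flat_features(self) -> np.ndarray:
        """Features as an (N, prod(shape)) matrix, row-major per sample."""
        return self.features.reshape(self.n_samples, -1)

    def subset(self, idx) -> "MultiLabelDataset":
        idx = np.asarray(idx)
        return MultiLabelDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            ids=[self.ids[i] for i in idx],
            label_names=list(self.label_names),
            synthetic=self.synthetic[idx],
            manifest=dict(self.manifest),
        )

    def concat(self, other: "MultiLabelDataset") -> "MultiLabelDataset":
        if other.label_names != self.label_names:
            raise ValueError("label vocabularies differ")
        if other.feature_shape != self.feature_shape:
            raise ValueError("feature shapes differ")
        return MultiLabelDataset(
            features=np.concatenate([self.features, other.features]),
            labels=np.concatenate([self.labels, other.labels]),
            ids=self.ids + other.ids,
            label_names=list(self.label_names),
            synthetic=np.concatenate([self.synthetic, other.synthetic]),
            manifest=dict(self.manifest),
        )

    def save(self, path: str | Path) -> None:
        """Write features/labels as NPZ plus a JSON manifest sidecar."""
        path = Path(path)
        np.savez(path, features=self.features, labels=self.labels,
                 synthetic=self.synthetic)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({
            "ids": self.ids,
            "label_names": self.label_names,
            "manifest": self.manifest,
        }, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MultiLabelDataset":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        arrays = np.load(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(features=arrays["features"], labels=arrays["labels"],
                   ids=meta["ids"], label_names=meta["label_names"],
                   synthetic=arrays["synthetic"], manifest=meta["manifest"])
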