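"""PSI-BLAST ASCII PSSM parsing and fixed-size featurization.

A PSSM for a protein of length L is an L x 20 matrix of log-odds
scores E[i, j]: the score of the residue at position i mutating to
amino-acid type j over evolution. Variable L is collapsed to a fixed
20 x 20 matrix so that downstream models see a uniform shape:

* ``grouped20x20`` (default): entry (a, j) is the mean of E[i, j] over
  positions i whose residue is type a — the standard "PSSM
  composition" encoding, which preserves a genuine 2-D structure for
  convolutional models.
* ``column_mean20``: the plain per-column mean over all positions,
  a 20-vector placed in row 0 with the remaining rows at the fill
  value of 0.

Rows for residue types absent from the sequence are filled with 0
(the neutral log-odds score). Non-standard residues (X/B/Z/U) have no
row in the grouped encoding; they are counted and contribute only to
the column mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AA_ORDER", "ProteinRecord", "PSSMMatrix", "FeatureMatrix",
    "FeatureScaler", "PSSMParseError", "parse_pssm_ascii",
    "pssm_to_ascii", "discretize_pssm", "fit_scaler", "apply_scaler",
    "load_labels_tsv", "write_feature_container", "read_feature_container",
]

#: Canonical amino-acid column ordering used by PSI-BLAST output.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
NONSTANDARD = set("XBZUJO*-")


class PSSMParseError(ValueError):
    pass


@dataclass
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PSSMMatrix:
    protein_id: str
    residues: str                 # length L
    scores: np.ndarray            # (L, 20) log-odds
    column_order: str = AA_ORDER
    n_nonstandard: int = 0        # residues outside the 20-letter alphabet

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        L = len(self.residues)
        if self.scores.shape != (L, 20):
            raise ValueError(
                f"scores shape {self.scores.shape} does not match L={L} x 20")
        if sorted(self.column_order) != sorted(AA_ORDER):
            raise ValueError("column_order must be a permutation of the 20 standard amino acids")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class FeatureMatrix:
    protein_id: str
    values: np.ndarray            # (20, 20); rows residue type, cols target type

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20, 20):
            raise ValueError(f"feature matrix must be 20x20, got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")

    def flatten(self) -> np.ndarray:
        """Row-major 400-vector."""
        return self.values.reshape(-1)


def parse_pssm_ascii(text: str, protein_id: str = "") -> PSSMMatrix:
    """Parse the per-query ASCII PSSM emitted by PSI-BLAST.

    Only the first 20 numeric columns (the log-odds block) are kept;
    trailing weighted-percentage and information-content columns, the
    two header lines and any statistics footer are ignored.
    """
    lines = text.splitlines()
    column_order = None
    residues: list[str] = []
    rows: list[list[float]] = []
    positions: list[int] = []
    in_data = False
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            if in_data:
                break  # blank line after the data block starts the footer
            continue
        if column_order is None:
            if len(tokens) >= 20 and all(len(t) == 1 and t.isalpha() for t in tokens[:20]):
                order = "".join(tokens[:20]).upper()
                if sorted(order) == sorted(AA_ORDER):
                    column_order = order
            continue
        # data rows start with a position index
        try:
            pos = int(tokens[0])
        except ValueError:
            if in_data:
                break  # footer (lambda/K statistics lines)
            continue
        in_data = True
        if len(tokens) < 22:
            raise PSSMParseError(
                f"line {lineno}: expected position, residue and 20 scores, "
                f"got {len(tokens)} tokens")
        residue = tokens[1].upper()
        if len(residue) != 1 or not residue.isalpha():
            raise PSSMParseError(f"line {lineno}: bad residue token {tokens[1]!r}")
        try:
            scores = [float(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise PSSMParseError(f"line {lineno}: non-numeric score ({exc})") from None
        if positions and pos != positions[-1] + 1:
            raise PSSMParseError(
                f"line {lineno}: position index {pos} is not consecutive "
                f"(previous was {positions[-1]})")
        positions.append(pos)
        residues.append(residue)
        rows.append(scores)
    if column_order is None:
        raise PSSMParseError("no amino-acid column-label line found")
    if not rows:
        raise PSSMParseError("no data rows found (empty PSSM)")
    n_nonstd = sum(1 for r in residues if r in NONSTANDARD or r not in AA_ORDER)
    return PSSMMatrix(protein_id=protein_id, residues="".join(residues),
                      scores=np.array(rows), column_order=column_order,
                      n_nonstandard=n_nonstd)


def pssm_to_ascii(pssm: PSSMMatrix) -> str:
    """Serialize in the dialect parse_pssm_ascii accepts (round-trips)."""
    out = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "   ".join(pssm.column_order),
    ]
    for i, (res, row) in enumerate(zip(pssm.residues, pssm.scores), start=1):
        cells = " ".join(f"{int(v):4d}" if float(v).is_integer() else f"{v:6.2f}"
                         for v in row)
        out.append(f"{i:5d} {res}  {cells}")
    out += ["", "                      K         Lambda"]
    return "\n".join(out) + "\n"


def discretize_pssm(pssm: PSSMMatrix, mode: str = "grouped20x20",
                    fill_value: float = 0.0) -> FeatureMatrix:
    """Collapse an L x 20 PSSM to the fixed 20 x 20 feature matrix."""
    if pssm.length == 0:
        raise ValueError("empty PSSM")
    # permute columns to the canonical ordering
    perm = [pssm.column_order.index(a) for a in AA_ORDER]
    scores = pssm.scores[:, perm]
    values = np.full((20, 20), fill_value, dtype=float)
    if mode == "column_mean20":
        values[0] = scores.mean(axis=0)
    elif mode == "grouped20x20":
        res_idx = np.array([AA_ORDER.find(r) for r in pssm.residues])
        for a in range(20):
            mask = res_idx == a
            if mask.any():
                values[a] = scores[mask].mean(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return FeatureMatrix(protein_id=pssm.protein_id, values=values)


@dataclass
class FeatureScaler:
    """Per-feature standardization fitted on training data only."""

    mean: np.ndarray = None
    scale: np.ndarray = None

    @property
    def fitted(self) -> bool:
        return self.mean is not None

    def fit(self, x: np.ndarray) -> "FeatureScaler":
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[0] == 0:
            raise ValueError("fit expects a non-empty (n_samples, n_features) matrix")
        self.mean = x.mean(axis=0)
        sd = x.std(axis=0)
        # zero-variance features pass through centred; the threshold is
        # relative so constant columns hit it despite rounding
        tiny = 1e-10 * np.maximum(1.0, np.abs(self.mean))
        sd[sd <= tiny] = 1.0
        self.scale = sd
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("scaler has not been fitted")
        return (np.asarray(x, dtype=float) - self.mean) / self.scale

    def inverse_transform(self, x: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("scaler has not been fitted")
        return np.asarray(x, dtype=float) * self.scale + self.mean

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(mean=np.array(d["mean"]), scale=np.array(d["scale"]))


def fit_scaler(train: list[FeatureMatrix] | np.ndarray) -> FeatureScaler:
    if isinstance(train, (list, tuple)):
        if not train:
            raise ValueError("cannot fit a scaler on an empty training set")
        train = np.stack([f.flatten() for f in train])
    return FeatureScaler().fit(np.asarray(train))


def apply_scaler(scaler: FeatureScaler, x: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(x, FeatureMatrix):
        x = x.flatten()
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    out = scaler.transform(x[None] if single else x)
    return out[0] if single else out


def load_labels_tsv(path: str | Path) -> tuple[dict[str, list[str]], list[str]]:
    """Read a TSV of protein_id <tab> semicolon-separated locations.

    Returns (id -> location list, sorted label vocabulary). A header
    line starting with 'protein_id' is skipped.
    """
    mapping: dict[str, list[str]] = {}
    vocab: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if lineno == 1 and parts[0].strip().lower() == "protein_id":
            continue
        if len(parts) < 2:
            raise ValueError(f"labels line {lineno}: expected 2 tab-separated fields")
        pid = parts[0].strip()
        locs = [l.strip() for l in parts[1].split(";") if l.strip()]
        if not locs:
            raise ValueError(f"labels line {lineno}: protein {pid!r} has no locations")
        if pid in mapping:
            raise ValueError(f"labels line {lineno}: duplicate protein id {pid!r}")
        mapping[pid] = locs
        vocab.update(locs)
    return mapping, sorted(vocab)


def write_feature_container(path: str | Path, ids: list[str],
                            features: np.ndarray, label_names: list[str],
                            labels: np.ndarray,
                            scaler: FeatureScaler | None = None) -> None:
    """Dense NPZ feature container with a JSON sidecar manifest."""
    path = Path(path)
    np.savez(path, features=np.asarray(features), labels=np.asarray(labels))
    manifest = {"protein_order": list(ids), "label_vocabulary": list(label_names)}
    if scaler is not None and scaler.fitted:
        manifest["scaler"] = scaler.to_dict()
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def read_feature_container(path: str | Path):
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    arrays = np.load(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    scaler = (FeatureScaler.from_dict(manifest["scaler"])
              if "scaler" in manifest else None)
    return (manifest["protein_order"], arrays["features"],
            manifest["label_vocabulary"], arrays["labels"], scaler)
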