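"""Core sample-by-feature container shared by generators, splitters and experiments.

A :class:`LabeledTable` is the in-memory currency of the package: a dense
feature matrix with one binary label per row, plus three identifier columns
that make leakage auditable,

``patient_id``
    the patient a row belongs to (several rows may share one patient),
``source_id``
    the acquisition source / batch a row came from (may be ``None``),
``provenance_id``
    the original sample a row descends from.  A row that is not a duplicate
    or an augmented copy has ``provenance_id == sample_id``; oversampling and
    augmentation propagate the origin's ``provenance_id`` to every copy, so
    correlated copies remain traceable across train/validation/test subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabeledTable"]


def _as_str_array(values, n: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=object)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got shape {arr.shape}")
    return arr


@dataclass
class LabeledTable:
    """Feature matrix with binary labels and leakage-tracking identifiers."""

    features: np.ndarray
    labels: np.ndarray
    patient_id: np.ndarray
    sample_id: np.ndarray = field(default=None)  # type: ignore[assignment]
    source_id: np.ndarray | None = None
    provenance_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n = self.features.shape[0]
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (n,):
            raise ValueError("labels must be a vector of length n_samples")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        self.patient_id = _as_str_array(self.patient_id, n, "patient_id")
        if any(not str(p) for p in self.patient_id):
            raise ValueError("every sample needs a nonempty patient_id")
        if self.sample_id is None:
            self.sample_id = np.array([f"S{i}" for i in range(n)], dtype=object)
        else:
            self.sample_id = _as_str_array(self.sample_id, n, "sample_id")
        if self.provenance_id is None:
            self.provenance_id = self.sample_id.copy()
        else:
            self.provenance_id = _as_str_array(self.provenance_id, n, "provenance_id")
        if self.source_id is not None:
            self.source_id = _as_str_array(self.source_id, n, "source_id")

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def take(self, indices) -> "LabeledTable":
        """Row-subset the table (copies; positional indices)."""
        idx = np.asarray(indices, dtype=int)
        return LabeledTable(
            features=self.features[idx].copy(),
            labels=self.labels[idx].copy(),
            patient_id=self.patient_id[idx].copy(),
            sample_id=self.sample_id[idx].copy(),
            source_id=None if self.source_id is None else self.source_id[idx].copy(),
            provenance_id=self.provenance_id[idx].copy(),
        )

    def select_features(self, feature_indices) -> "LabeledTable":
        """Column-subset the feature matrix, keeping all metadata."""
        idx = np.asarray(feature_indices, dtype=int)
        return LabeledTable(
            features=self.features[:, idx].copy(),
            labels=self.labels.copy(),
            patient_id=self.patient_id.copy(),
            sample_id=self.sample_id.copy(),
            source_id=None if self.source_id is None else self.source_id.copy(),
            provenance_id=self.provenance_id.copy(),
        )

    def class_counts(self) -> tuple[int, int]:
        """(negative, positive) sample counts."""
        pos = int(self.labels.sum())
        return len(self) - pos, pos

    # -- CSV round-trip ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols = {f"feature_{j}": self.features[:, j] for j in range(self.n_features)}
        cols["label"] = self.labels
        cols["patient_id"] = self.patient_id
        cols["sample_id"] = self.sample_id
        cols["source_id"] = (
            self.source_id if self.source_id is not None else [""] * len(self)
        )
        cols["provenance_id"] = self.provenance_id
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LabeledTable":
        feature_cols = [c for c in frame.columns if c.startswith("feature_")]
        feature_cols.sort(key=lambda c: int(c.split("_", 1)[1]))
        source = frame["source_id"].astype(str).to_numpy(dtype=object)
        has_source = any(s not in ("", "nan") for s in source)
        return cls(
            features=frame[feature_cols].to_numpy(dtype=float),
            labels=frame["label"].to_numpy(dtype=int),
            patient_id=frame["patient_id"].astype(str).to_numpy(dtype=object),
            sample_id=frame["sample_id"].astype(str).to_numpy(dtype=object),
            source_id=source if has_source else None,
            provenance_id=frame["provenance_id"].astype(str).to_numpy(dtype=object),
        )

    @classmethod
    def from_csv(cls, path) -> "LabeledTable":
        return cls.from_frame(pd.read_csv(path))

    @staticmethod
    def concat(tables: list["LabeledTable"]) -> "LabeledTable":
        if not tables:
            raise ValueError("need at least one table")
        has_source = any(t.source_id is not None for t in tables)
        return LabeledTable(
            features=np.vstack([t.features for t in tables]),
            labels=np.concatenate([t.labels for t in tables]),
            patient_id=np.concatenate([t.patient_id for t in tables]),
            sample_id=np.concatenate([t.sample_id for t in tables]),
            source_id=(
                np.concatenate(
                    [
                        t.source_id
                        if t.source_id is not None
                        else np.array([""] * len(t), dtype=object)
                        for t in tables
                    ]
                )
                if has_source
                else None
            ),
            provenance_id=np.concatenate([t.provenance_id for t in tables]),
        )
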