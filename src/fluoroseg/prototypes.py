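"""Labeled multi-prototype sets.

A trained model is nothing more than a matrix of cluster centroids in the
six-dimensional feature space plus one color-class label per centroid.
One class is typically represented by many prototypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .color_features import FEATURE_NAMES
from .labels import CLASS_CODES, CLASS_NAMES


@dataclass
class PrototypeSet:
    centroids: np.ndarray            # (N_C, 6)
    labels: np.ndarray               # (N_C,) int codes into CLASS_NAMES
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=np.float64))
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if self.centroids.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per centroid required")

    def __len__(self) -> int:
        return self.centroids.shape[0]

    @property
    def class_counts(self) -> dict:
        counts = np.bincount(self.labels, minlength=len(CLASS_NAMES))
        return {name: int(c) for name, c in zip(CLASS_NAMES, counts)}

    def subset(self, keep_labels) -> "PrototypeSet":
        """Prototypes restricted to the given class codes."""
        keep = np.isin(self.labels, np.asarray(list(keep_labels)))
        if not keep.any():
            raise ValueError("no prototypes left after restriction")
        return PrototypeSet(self.centroids[keep], self.labels[keep], dict(self.metadata))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.centroids, columns=list(FEATURE_NAMES))
        df["label"] = np.asarray(CLASS_NAMES, dtype=object)[self.labels]
        return df

    def save(self, csv_path, json_path=None) -> None:
        """Write the centroid table as CSV plus an optional JSON sidecar."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            meta = {k: v for k, v in self.metadata.items()}
            meta["n_prototypes"] = len(self)
            meta["class_counts"] = self.class_counts
            Path(json_path).write_text(json.dumps(meta, indent=2, default=float))

    @classmethod
    def load(cls, csv_path) -> "PrototypeSet":
        df = pd.read_csv(csv_path)
        missing = [c for c in (*FEATURE_NAMES, "label") if c not in df.columns]
        if missing:
            raise ValueError(f"prototype CSV missing columns: {missing}")
        labels = df["label"].map(CLASS_CODES)
        if labels.isna().any():
            bad = sorted(set(df["label"]) - set(CLASS_NAMES))
            raise ValueError(f"unknown class labels in prototype CSV: {bad}")
        return cls(df[list(FEATURE_NAMES)].to_numpy(), labels.to_numpy())
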