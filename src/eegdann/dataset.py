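"""In-memory feature dataset shared by training, evaluation and the CLI.

Stores the per-window 62 x 5 DE matrices once; the two model-facing views
(channels-first activity maps and graph node features) are derived after
normalisation, so train-split z-scoring propagates consistently to both
branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layout_features import (
    BandScheme,
    DEFeatureMatrix,
    ElectrodeLayout,
    RawRecording,
    build_adjacency,
    compute_de_features,
)

__all__ = ["FeatureDataset", "Normalizer", "features_from_recordings"]


@dataclass
class Normalizer:
    """Per-(electrode, band) z-score parameters fit on a training split."""

    mean: np.ndarray  # (62, 5)
    std: np.ndarray  # (62, 5)

    @classmethod
    def fit(cls, de: np.ndarray) -> "Normalizer":
        mean = de.mean(axis=0)
        std = de.std(axis=0)
        std = np.where(std > 1e-12, std, 1.0)
        return cls(mean=mean, std=std)

    @classmethod
    def identity(cls, shape=(62, 5)) -> "Normalizer":
        return cls(mean=np.zeros(shape), std=np.ones(shape))

    def apply(self, de: np.ndarray) -> np.ndarray:
        return (de - self.mean) / self.std


class FeatureDataset:
    """Windows x electrodes x bands DE features with labels and subjects."""

    def __init__(
        self,
        de: np.ndarray,
        labels: np.ndarray,
        subjects: np.ndarray,
        layout: ElectrodeLayout,
        adjacency: np.ndarray,
        scheme: BandScheme | None = None,
    ):
        self.de = np.asarray(de, dtype=np.float64)
        self.labels = np.asarray(labels, dtype=np.int64)
        self.subjects = np.asarray(subjects)
        self.layout = layout
        self.adjacency = np.asarray(adjacency, dtype=np.float64)
        self.scheme = scheme or BandScheme()
        if self.de.ndim != 3:
            raise ValueError("de must be (n_windows, n_electrodes, n_bands)")
        n = self.de.shape[0]
        if not (len(self.labels) == len(self.subjects) == n):
            raise ValueError("labels/subjects must align with windows")

    def __len__(self) -> int:
        return self.de.shape[0]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def subject_ids(self) -> list:
        seen = []
        for s in self.subjects:
            if s not in seen:
                seen.append(s)
        return seen

    def subset(self, mask: np.ndarray) -> "FeatureDataset":
        return FeatureDataset(
            self.de[mask], self.labels[mask], self.subjects[mask],
            self.layout, self.adjacency, self.scheme,
        )

    def split_by_subjects(self, subjects) -> "FeatureDataset":
        keep = set(subjects)
        mask = np.array([s in keep for s in self.subjects])
        return self.subset(mask)

    def model_views(self, normalizer: Normalizer | None = None):
        """Return (maps, node_features) after optional normalisation.

        maps: (N, B, H, W) channels-first activity maps;
        node_features: (N, V, B) graph node features.
        """
        de = self.de if normalizer is None else normalizer.apply(self.de)
        n, ne, nb = de.shape
        lay = self.layout
        maps = np.zeros((n, nb, lay.height, lay.width))
        rows = np.array([rc[0] for rc in lay.grid_coords])
        cols = np.array([rc[1] for rc in lay.grid_coords])
        maps[:, :, rows, cols] = de.transpose(0, 2, 1)
        return maps, de.copy()


def features_from_recordings(
    recordings: list[RawRecording],
    scheme: BandScheme | None = None,
    layout: ElectrodeLayout | None = None,
    adjacency_rule: str = "knn",
    adjacency_param: float = 4,
    window_seconds: float = 4.0,
) -> FeatureDataset:
    """Run the DE pipeline over a list of labeled trials."""
    scheme = scheme or BandScheme()
    layout = layout or ElectrodeLayout.default()
    adjacency = build_adjacency(layout, adjacency_rule, adjacency_param)
    de, labels, subjects = [], [], []
    for rec in recordings:
        feats: list[DEFeatureMatrix] = compute_de_features(
            rec, scheme, layout, window_seconds=window_seconds
        )
        for f in feats:
            de.append(f.values)
            labels.append(-1 if f.label is None else f.label)
            subjects.append(f.subject_id)
    return FeatureDataset(
        np.stack(de), np.array(labels), np.array(subjects), layout, adjacency, scheme
    )
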