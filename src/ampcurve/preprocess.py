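"""Feature normalization and 2-D principal-component projection.

Normalization is per-feature z-scoring fitted on the training split only;
zero-variance features keep their location but get unit scale so they map to
zero instead of dividing by zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .simgen import FluorescenceCurve, LabeledDataset

__all__ = ["NormalizerState", "normalize_fit", "normalize_apply", "pca_project"]


@dataclass(frozen=True)
class NormalizerState:
    """Per-feature location (mean) and scale (sd) learned from training data."""

    location: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        loc = np.asarray(self.location, dtype=float)
        sc = np.asarray(self.scale, dtype=float)
        object.__setattr__(self, "location", loc)
        object.__setattr__(self, "scale", sc)
        if loc.shape != sc.shape or loc.ndim != 1:
            raise ValueError("location and scale must be 1-D and equal length")
        if np.any(sc <= 0):
            raise ValueError("scale values must be > 0")

    def __len__(self) -> int:
        return len(self.location)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != len(self):
            raise ValueError(
                f"feature length {X.shape[-1]} != normalizer length {len(self)}"
            )
        return (X - self.location) / self.scale

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        if Z.shape[-1] != len(self):
            raise ValueError(
                f"feature length {Z.shape[-1]} != normalizer length {len(self)}"
            )
        return Z * self.scale + self.location

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"location": self.location.tolist(), "scale": self.scale.tolist()},
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "NormalizerState":
        with open(path) as fh:
            d = json.load(fh)
        return cls(location=np.array(d["location"]), scale=np.array(d["scale"]))


def normalize_fit(train: LabeledDataset) -> NormalizerState:
    """Learn per-feature mean/sd z-scoring parameters from a training set."""
    if len(train) == 0:
        raise ValueError("cannot fit a normalizer on an empty dataset")
    X = train.feature_matrix()
    location = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)  # zero-variance convention
    return NormalizerState(location=location, scale=scale)


def normalize_apply(
    state: NormalizerState, curve: FluorescenceCurve | np.ndarray
) -> np.ndarray:
    """Elementwise ``(value - location) / scale`` for one curve."""
    values = curve.rfu if isinstance(curve, FluorescenceCurve) else np.asarray(curve)
    return state.transform(values)


def pca_project(
    ds: LabeledDataset, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered projection of the raw feature matrix onto the top
    principal components.

    Returns ``(coords, explained_variance)`` with components ordered by
    descending explained variance. Sign convention: each component is flipped
    so its largest-magnitude loading is positive, making plots reproducible.
    """
    X = ds.feature_matrix()
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds the number of features")
    if X.shape[0] < n_components:
        raise ValueError("need at least n_components samples")
    if np.allclose(X, X[0]):
        # degenerate corpus: no variance anywhere
        return np.zeros((X.shape[0], n_components)), np.zeros(n_components)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(n_components):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, j] *= -1
    return coords, pca.explained_variance_
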