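"""Probabilistic neural network (PNN): Parzen-window classifier.

The classic four-layer topology: an input layer, a pattern layer holding
every training vector as a kernel centre, a summation layer pooling the
kernel responses per class,

    H_k(x) = sum_i exp(-||x - c_ki||^2 / (2 sigma^2)),

and an output layer combining the pooled responses through class-mixing
weights, Y_j = sum_k w_jk H_k(x), with the predicted label argmax_j Y_j.
Under the default wiring w_jk = delta_jk / n_j, so Y_j is the mean kernel
density of class j at x.  Training is deterministic storage — there is no
iterative optimisation.

There is one shared isotropic Gaussian bandwidth sigma.  Because band
energies span orders of magnitude across wavelet scales, features are
z-scored (statistics fitted on the training set) before kernel distances
by default.

Scores are evaluated in the log domain, so the sigma -> 0 limit degrades
gracefully to 1-nearest-neighbour classification instead of underflowing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.model_selection import StratifiedKFold

from .wavelets import FeatureVector

__all__ = [
    "PNNModel",
    "Prediction",
    "fit",
    "pattern_response",
    "classify",
    "select_sigma",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1


def _as_matrix(features) -> tuple[np.ndarray, list[str]]:
    """Accept FeatureVectors or a (X, labels) pair; return X, labels."""
    if isinstance(features, tuple) and len(features) == 2:
        X = np.asarray(features[0], dtype=float)
        labels = [str(l) for l in features[1]]
        return X, labels
    fvs: Sequence[FeatureVector] = list(features)
    X = np.vstack([fv.values for fv in fvs])
    labels = [str(fv.label) for fv in fvs]
    return X, labels


@dataclass
class PNNModel:
    """Stored centres, bandwidth, and class-mixing weights."""

    class_names: list[str]
    centers: list[np.ndarray]  # centers[k]: (n_k, d) array, class order
    sigma: float
    weights: np.ndarray  # (M, M): Y_j = sum_k weights[j, k] * H_k
    standardize: bool = True
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not self.centers or any(c.shape[0] < 1 for c in self.centers):
            raise ValueError("every class needs at least one centre")

    @property
    def M(self) -> int:
        return len(self.class_names)

    @property
    def n_k(self) -> tuple[int, ...]:
        return tuple(c.shape[0] for c in self.centers)

    @property
    def dim(self) -> int:
        return self.centers[0].shape[1]

    def _transform(self, x: np.ndarray) -> np.ndarray:
        if self.standardize:
            return (x - self.feature_mean) / self.feature_scale
        return x


@dataclass(frozen=True)
class Prediction:
    label: str
    scores: np.ndarray  # Y_j per class (may underflow to 0 for tiny sigma)
    posteriors: np.ndarray  # scores normalised to sum 1


def fit(features, sigma: float = 1.0, standardize: bool = True) -> PNNModel:
    """Store labelled feature vectors as Parzen kernel centres.

    ``features`` is either a sequence of labelled FeatureVectors or an
    ``(X, labels)`` pair.  Classes are ordered by first appearance.
    Default mixing weights connect each output unit only to its own
    class's pattern units, scaled 1/n_j.
    """
    X, labels = _as_matrix(features)
    if not np.all(np.isfinite(X)):
        raise ValueError("NaN or infinite feature values")
    class_names = list(dict.fromkeys(labels))
    if len(class_names) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: labels.count(c) for c in class_names}
    if min(counts.values()) < 1:  # pragma: no cover - unreachable by construction
        raise ValueError("class with zero samples")

    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    Xt = (X - mean) / scale if standardize else X

    y = np.array(labels)
    centers = [Xt[y == c] for c in class_names]
    M = len(class_names)
    weights = np.diag([1.0 / c.shape[0] for c in centers])
    return PNNModel(
        class_names=class_names,
        centers=centers,
        sigma=float(sigma),
        weights=weights,
        standardize=standardize,
        feature_mean=mean if standardize else None,
        feature_scale=scale if standardize else None,
    )


def _sq_distances(model: PNNModel, x: np.ndarray) -> list[np.ndarray]:
    x = np.asarray(x, dtype=float)
    if x.shape != (model.dim,):
        raise ValueError(
            f"feature dimension mismatch: expected {model.dim}, got {x.shape}"
        )
    xt = model._transform(x)
    return [np.sum((c - xt) ** 2, axis=1) for c in model.centers]


def pattern_response(model: PNNModel, x) -> np.ndarray:
    """Summation-layer outputs H_k(x) = sum_i exp(-d_ki^2 / (2 sigma^2))."""
    if isinstance(x, FeatureVector):
        x = x.values
    d2 = _sq_distances(model, x)
    return np.array(
        [float(np.exp(-d / (2.0 * model.sigma**2)).sum()) for d in d2]
    )


def _log_scores(model: PNNModel, x: np.ndarray) -> np.ndarray:
    """log Y_j, evaluated stably for arbitrarily small sigma."""
    d2 = _sq_distances(model, x)
    log_h = np.array([logsumexp(-d / (2.0 * model.sigma**2)) for d in d2])
    shift = log_h.max()
    h_shifted = np.exp(log_h - shift)  # max entry is 1
    yv = model.weights @ h_shifted
    with np.errstate(divide="ignore"):
        return shift + np.log(yv)


def classify(model: PNNModel, x) -> Prediction:
    """Output-layer decision: label = argmax_j Y_j (ties -> lowest index)."""
    if isinstance(x, FeatureVector):
        x = x.values
    log_y = _log_scores(model, np.asarray(x, dtype=float))
    idx = int(np.argmax(log_y))
    posteriors = np.exp(log_y - logsumexp(log_y))
    posteriors = posteriors / posteriors.sum()
    with np.errstate(over="ignore"):
        scores = np.exp(log_y)
    return Prediction(
        label=model.class_names[idx], scores=scores, posteriors=posteriors
    )


def classify_batch(model: PNNModel, X: np.ndarray) -> list[str]:
    """Labels for a feature matrix (rows = samples)."""
    return [classify(model, row).label for row in np.asarray(X, dtype=float)]


def select_sigma(
    features,
    candidates: Sequence[float],
    folds: int = 5,
    standardize: bool = True,
    seed: int = 0,
) -> float:
    """Pick the kernel bandwidth by stratified cross-validated accuracy.

    Returns the candidate with the highest mean CV accuracy; ties go to
    the smaller sigma.  Deterministic given ``seed``.
    """
    candidates = sorted(float(s) for s in candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate sigmas")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X, labels = _as_matrix(features)
    y = np.array(labels)
    counts = pd.Series(y).value_counts()
    if counts.min() < folds:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} samples < {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best_sigma, best_acc = candidates[0], -1.0
    for sigma in candidates:
        correct = total = 0
        for train_idx, val_idx in skf.split(X, y):
            model = fit((X[train_idx], y[train_idx]), sigma, standardize)
            pred = classify_batch(model, X[val_idx])
            correct += int(np.sum(np.array(pred) == y[val_idx]))
            total += val_idx.size
        acc = correct / total
        if acc > best_acc:  # strict: ties keep the smaller (earlier) sigma
            best_sigma, best_acc = sigma, acc
    return best_sigma


# ---------------------------------------------------------------------------
# Serialization: manifest JSON + centres CSV in a directory
# ---------------------------------------------------------------------------

def save_model(model: PNNModel, path: str | Path) -> Path:
    """Write a model as <path>/manifest.json + <path>/centers.csv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": _FORMAT_VERSION,
        "class_names": model.class_names,
        "n_k": list(model.n_k),
        "sigma": model.sigma,
        "weights": model.weights.tolist(),
        "standardize": model.standardize,
        "feature_mean": None
        if model.feature_mean is None
        else model.feature_mean.tolist(),
        "feature_scale": None
        if model.feature_scale is None
        else model.feature_scale.tolist(),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    rows = []
    for name, c in zip(model.class_names, model.centers):
        for row in c:
            rows.append([name, *row])
    df = pd.DataFrame(rows, columns=["label", *(f"f{i}" for i in range(model.dim))])
    df.to_csv(path / "centers.csv", index=False, float_format="%.17g")
    return path


def load_model(path: str | Path) -> PNNModel:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest["format_version"] != _FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {manifest['format_version']}"
        )
    df = pd.read_csv(path / "centers.csv")
    centers = [
        df[df["label"] == name].iloc[:, 1:].to_numpy(dtype=float)
        for name in manifest["class_names"]
    ]
    return PNNModel(
        class_names=manifest["class_names"],
        centers=centers,
        sigma=manifest["sigma"],
        weights=np.array(manifest["weights"]),
        standardize=manifest["standardize"],
        feature_mean=None
        if manifest["feature_mean"] is None
        else np.array(manifest["feature_mean"]),
        feature_scale=None
        if manifest["feature_scale"] is None
        else np.array(manifest["feature_scale"]),
    )
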