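"""Pixel-level exposure classifiers and sample-level majority voting.

Input features are the preprocessed spectra restricted to the fingerprint
[900, 1800] and CH-stretch [2800, 3050] cm^-1 ranges. Five model families
are supported: L1- and L2-regularized logistic regression, a linear SVM, a
fully-connected net and a 1-D CNN (the two nets are the numpy classifiers
from :mod:`ftir_radsig.nn`). Training happens at the pixel level; sample
predictions are the majority vote of a sample's pixels, with the positive
vote fraction doubling as the sample-level continuous score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupShuffleSplit
from sklearn.svm import LinearSVC

from .io import PixelPool
from .nn import CNN1DClassifier, FCNNClassifier

__all__ = [
    "FeatureSpec",
    "ModelSpec",
    "MODEL_FAMILIES",
    "build_features",
    "make_classifier",
    "train_model",
    "select_penalty",
    "lasso_selected_wavenumbers",
    "majority_vote",
    "predict_pool",
    "PredictionResult",
]

MODEL_FAMILIES = ("lasso_lr", "ridge_lr", "svm", "fcnn", "cnn1d")


@dataclass(frozen=True)
class FeatureSpec:
    """Wavenumber ranges concatenated into the feature vector.

    Column order is descending wavenumber within each range, ranges in the
    listed order; ``source`` documents that features come from preprocessed
    (baseline-corrected, normalized) spectra.
    """

    ranges: tuple = ((900.0, 1800.0), (2800.0, 3050.0))
    source: str = "preprocessed"

    def __post_init__(self) -> None:
        ivs = sorted(self.ranges)
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if b1 > a2:
                raise ValueError(f"feature ranges overlap: {ivs}")


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family plus its hyperparameters."""

    family: str = "lasso_lr"
    penalty_strength: float = 1.0  # inverse-regularization C for linear models
    architecture: dict = field(default_factory=dict)  # nn families
    epochs: int = 25
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"family must be one of {MODEL_FAMILIES}, got {self.family!r}"
            )
        if self.penalty_strength <= 0:
            raise ValueError("penalty_strength must be positive")


def build_features(pool: PixelPool, spec: FeatureSpec = FeatureSpec(),
                   label_mode: str = "binary"
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature matrix, label vector, and per-column wavenumbers.

    Labels: ``binary`` gives exposed = dose > 0; ``dose`` gives the dose in
    Gy as a multi-class label.
    """
    from .io import slice_band

    blocks, waves = [], []
    for lo, hi in spec.ranges:
        sub, sub_axis = slice_band(pool.spectra, pool.axis, lo, hi)
        blocks.append(sub)
        waves.append(sub_axis)
    X = np.concatenate(blocks, axis=1)
    feature_waves = np.concatenate(waves)
    if label_mode == "binary":
        y = pool.exposed_labels()
    elif label_mode == "dose":
        y = pool.records["dose_gy"].to_numpy()
    else:
        raise ValueError(f"unknown label_mode {label_mode!r}")
    return X, y, feature_waves


def make_classifier(spec: ModelSpec):
    """Unfitted sklearn-style estimator for a model spec."""
    if spec.family == "lasso_lr":
        return LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=spec.penalty_strength,
            max_iter=2000, random_state=spec.seed, class_weight="balanced",
        )
    if spec.family == "ridge_lr":
        return LogisticRegression(
            l1_ratio=0.0, solver="lbfgs", C=spec.penalty_strength,
            max_iter=2000, class_weight="balanced",
        )
    if spec.family == "svm":
        return LinearSVC(C=spec.penalty_strength, dual=False, max_iter=5000,
                         class_weight="balanced")
    arch = dict(spec.architecture)
    common = dict(epochs=spec.epochs, batch_size=spec.batch_size,
                  learning_rate=spec.learning_rate, random_state=spec.seed)
    if spec.family == "fcnn":
        return FCNNClassifier(**arch, **common)
    return CNN1DClassifier(**arch, **common)


def train_model(spec: ModelSpec, X: np.ndarray, y: np.ndarray):
    """Fit the requested family on pixel features; seeded and deterministic."""
    X = np.asarray(X)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes in y")
    return make_classifier(spec).fit(X, y)


def select_penalty(spec: ModelSpec, X, y, groups,
                   grid=(0.01, 0.1, 1.0, 10.0), val_fraction=0.25,
                   seed: int = 0) -> float:
    """Pick the penalty strength on a sample-grouped validation split.

    The split is carved from the training data at the sample level (no
    sample contributes pixels to both sides), avoiding the leakage of
    selecting on the test set. Returns the best strength by validation
    accuracy; ties break toward stronger regularization.
    """
    splitter = GroupShuffleSplit(n_splits=1, test_size=val_fraction,
                                 random_state=seed)
    (tr, va), = splitter.split(X, y, groups=groups)
    best, best_acc = None, -np.inf
    for c in sorted(grid):  # ascending C == descending regularization
        model = train_model(replace(spec, penalty_strength=float(c)),
                            X[tr], y[tr])
        acc = float(np.mean(model.predict(X[va]) == y[va]))
        if acc > best_acc:
            best, best_acc = float(c), acc
    return best


def lasso_selected_wavenumbers(model, feature_wavenumbers: np.ndarray
                               ) -> list[tuple[float, float]]:
    """Nonzero-coefficient wavenumbers, sorted by |coefficient| descending."""
    if not hasattr(model, "coef_"):
        raise ValueError("model is not a fitted linear classifier")
    coef = np.asarray(model.coef_).ravel()
    if coef.size != len(feature_wavenumbers):
        raise ValueError("coefficient/wavenumber length mismatch")
    nz = np.nonzero(coef)[0]
    order = nz[np.argsort(-np.abs(coef[nz]), kind="stable")]
    return [(float(feature_wavenumbers[i]), float(coef[i])) for i in order]


def pixel_scores(model, X: np.ndarray) -> np.ndarray:
    """P(exposed) per pixel; margin-based models go through a sigmoid."""
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        pos = list(model.classes_).index(1) if 1 in model.classes_ else -1
        return proba[:, pos]
    return expit(model.decision_function(X))


def majority_vote(pixel_labels: np.ndarray, sample_ids: np.ndarray,
                  tie_rule: str = "negative") -> pd.DataFrame:
    """Aggregate pixel labels to sample labels by majority vote.

    ``vote_fraction`` is the positive-pixel fraction (the sample-level
    continuous score). Exact ties predict unexposed under the default
    conservative rule; ``tie_rule="positive"`` flips that.
    """
    df = pd.DataFrame({"sample_id": sample_ids, "pos": pixel_labels})
    g = df.groupby("sample_id", sort=False)["pos"]
    out = pd.DataFrame({
        "sample_id": list(g.groups),
        "n_pixels": g.size().to_numpy(),
        "n_positive": g.sum().to_numpy(),
    })
    out["vote_fraction"] = out["n_positive"] / out["n_pixels"]
    if tie_rule == "negative":
        out["label"] = (out["vote_fraction"] > 0.5).astype(int)
    elif tie_rule == "positive":
        out["label"] = (out["vote_fraction"] >= 0.5).astype(int)
    else:
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    return out


@dataclass
class PredictionResult:
    """Pixel probabilities/labels plus sample-level vote table."""

    pixel_probs: np.ndarray
    pixel_labels: np.ndarray
    sample_votes: pd.DataFrame  # sample_id, n_pixels, n_positive,
    #                             vote_fraction, label + joined metadata


def predict_pool(model, pool: PixelPool, spec: FeatureSpec = FeatureSpec(),
                 tie_rule: str = "negative") -> PredictionResult:
    """Score every pixel in a pool and aggregate votes per sample."""
    X, _, _ = build_features(pool, spec)
    probs = pixel_scores(model, X)
    labels = (probs > 0.5).astype(int)
    votes = majority_vote(labels, pool.sample_ids, tie_rule=tie_rule)
    meta_cols = [c for c in ("dose_gy", "day", "split", "mouse_id")
                 if c in pool.records.columns]
    meta = pool.records[["sample_id", *meta_cols]].drop_duplicates("sample_id")
    votes = votes.merge(meta, on="sample_id", how="left")
    if "dose_gy" in votes.columns:
        votes["true_label"] = (votes["dose_gy"] > 0).astype(int)
    return PredictionResult(pixel_probs=probs, pixel_labels=labels,
                            sample_votes=votes)
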