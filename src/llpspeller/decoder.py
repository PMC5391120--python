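"""Shrinkage-regularized linear decoders for target/non-target epochs.

Two scikit-learn style estimators share the projection rule
w = Σ⁻¹(μ+ − μ−):

* :class:`LLPDecoder` — unsupervised. Class means are reconstructed from
  group means via the mean-map (no labels read); Σ is the Ledoit–Wolf
  shrinkage estimate of the *global* pooled covariance over all epochs.
* :class:`ShrinkageLDA` — the supervised baseline. Class means from
  labels; Σ is the pooled within-class shrinkage covariance.

Scores are plain projections f(x) = wᵀx with no bias: when every
selectable symbol is highlighted equally often per trial, a bias shifts
every symbol's score sum equally and cancels out of the arg-max.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator
from sklearn.covariance import ledoit_wolf
from sklearn.metrics import roc_auc_score

from .epochs import NONTARGET, TARGET, EpochSet
from .meanmap import (
    ClassMeans,
    MixingMatrix,
    estimate_group_means,
    reconstruct_class_means,
)

__all__ = [
    "shrinkage_covariance",
    "LLPDecoder",
    "ShrinkageLDA",
    "train_llp",
    "train_supervised",
    "score_epochs",
    "select_symbol",
    "auc",
    "save_model",
    "load_model",
]


def shrinkage_covariance(
    features: np.ndarray, assume_centered: bool = False
) -> tuple[np.ndarray, float]:
    """Ledoit–Wolf shrinkage covariance (1−γ)·S + γ·ν·I of an N×D matrix.

    S is the sample covariance (1/N convention), ν the average of its
    diagonal, and γ the analytic Ledoit–Wolf intensity clipped to [0, 1].
    Returns ``(covariance, gamma)``.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need an N x D matrix with N >= 2")
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain non-finite values")
    n, d = features.shape
    dof = n if assume_centered else n - 1
    if dof < 2:
        # the analytic intensity estimator has no degrees of freedom left
        # (it is identically 0 at n = 2 after centering, leaving a singular
        # rank-1 estimate); with no information about covariance structure,
        # shrink fully to the scaled-identity target
        if assume_centered:
            diag = np.einsum("ij,ij->j", features, features) / n
        else:
            centered = features - features.mean(axis=0)
            diag = np.einsum("ij,ij->j", centered, centered) / n
        return float(diag.mean()) * np.eye(d), 1.0
    cov, gamma = ledoit_wolf(features, assume_centered=assume_centered)
    return cov, float(gamma)


def _solve_weights(covariance: np.ndarray, mean_difference: np.ndarray) -> np.ndarray:
    """Solve Σw = μ+ − μ− with a symmetric positive-definite solver."""
    try:
        return scipy.linalg.solve(covariance, mean_difference, assume_a="pos")
    except scipy.linalg.LinAlgError:
        # shrinkage keeps Σ PD in practice; fall back for pathological input
        return np.linalg.lstsq(covariance, mean_difference, rcond=None)[0]


class _LinearEpochScorer(BaseEstimator):
    """Shared decision_function/predict for the two decoders."""

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got shape {X.shape}"
            )
        return X @ self.coef_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, TARGET, NONTARGET)


class LLPDecoder(_LinearEpochScorer):
    """Unsupervised LLP decoder: mean-map class means + pooled shrinkage LDA.

    Parameters
    ----------
    mixing : MixingMatrix or array-like of rows, optional
        Per-group (target, non-target) proportions. Defaults to the
        two-sequence speller mixing (3/8, 5/8; 2/18, 16/18).

    Fitted attributes
    -----------------
    coef_ : (D,) projection vector w = Σ⁻¹(μ+ − μ−)
    class_means_ : ClassMeans reconstructed via the mean-map
    group_means_ : GroupMeans of the fit data
    covariance_ : (D, D) global pooled shrinkage covariance
    shrinkage_ : Ledoit–Wolf intensity γ
    n_epochs_ : number of epochs the model was fitted on
    """

    def __init__(self, mixing: MixingMatrix | Sequence | None = None):
        self.mixing = mixing

    def _resolved_mixing(self) -> MixingMatrix:
        if self.mixing is None:
            return MixingMatrix.study_default()
        if isinstance(self.mixing, MixingMatrix):
            return self.mixing
        return MixingMatrix.from_rows(self.mixing)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LLPDecoder":
        """Fit from features ``X`` and per-epoch *group tags* ``y``.

        ``y`` carries proportion-group membership, never class labels.
        Tags are matched against the mixing matrix's group names when they
        coincide as sets, otherwise sorted tag order maps to row order.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        mixing = self._resolved_mixing()
        present = set(y.tolist())
        if present == set(mixing.group_names):
            order = list(mixing.group_names)
        elif len(present) == mixing.n_groups:
            order = sorted(present)
        else:
            raise ValueError(
                f"group tags {sorted(present)!r} do not match the "
                f"{mixing.n_groups}-group mixing matrix {mixing.group_names!r}"
            )
        epochs = EpochSet(features=X, group=y)
        self.group_means_ = estimate_group_means(epochs, group_order=order)
        self.class_means_ = reconstruct_class_means(self.group_means_, mixing)
        self.covariance_, self.shrinkage_ = shrinkage_covariance(X)
        self.coef_ = _solve_weights(self.covariance_, self.class_means_.difference)
        self.n_features_in_ = X.shape[1]
        self.n_epochs_ = X.shape[0]
        return self


class ShrinkageLDA(_LinearEpochScorer):
    """Supervised shrinkage-LDA baseline on labelled epochs.

    Parameters
    ----------
    pooling : {'weighted', 'unweighted'}
        How the two class-wise covariance matrices are pooled before
        shrinkage: weighted by class counts (default) or simple average.

    Fitted attributes mirror :class:`LLPDecoder` (class means come from
    labelled sample statistics instead of the mean-map).
    """

    def __init__(self, pooling: str = "weighted"):
        self.pooling = pooling

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShrinkageLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        pos, neg = y == TARGET, y == NONTARGET
        if not (pos | neg).all():
            raise ValueError("labels must be +1 (target) or -1 (non-target)")
        n_pos, n_neg = int(pos.sum()), int(neg.sum())
        if n_pos == 0 or n_neg == 0:
            raise ValueError("both classes must be present to fit the LDA")
        mu_pos = X[pos].mean(axis=0)
        mu_neg = X[neg].mean(axis=0)
        residuals = X.copy()
        residuals[pos] -= mu_pos
        residuals[neg] -= mu_neg
        if self.pooling == "unweighted":
            # rescale so the pooled covariance equals (S+ + S-)/2
            n = X.shape[0]
            residuals[pos] *= np.sqrt(n / (2.0 * n_pos))
            residuals[neg] *= np.sqrt(n / (2.0 * n_neg))
        elif self.pooling != "weighted":
            raise ValueError("pooling must be 'weighted' or 'unweighted'")
        self.covariance_, self.shrinkage_ = shrinkage_covariance(
            residuals, assume_centered=True
        )
        self.class_means_ = ClassMeans(target_mean=mu_pos, nontarget_mean=mu_neg)
        self.class_counts_ = (n_pos, n_neg)
        self.coef_ = _solve_weights(self.covariance_, self.class_means_.difference)
        self.n_features_in_ = X.shape[1]
        self.n_epochs_ = X.shape[0]
        return self


# -- thin functional wrappers over the estimators --------------------------


def train_llp(epochs: EpochSet, mixing: MixingMatrix | None = None) -> LLPDecoder:
    """Fit the unsupervised LLP decoder on an EpochSet (labels never read)."""
    return LLPDecoder(mixing=mixing).fit(epochs.features, epochs.group)


def train_supervised(epochs: EpochSet, pooling: str = "weighted") -> ShrinkageLDA:
    """Fit the supervised shrinkage-LDA baseline on a labelled EpochSet."""
    if epochs.label is None:
        raise ValueError("supervised training requires labels")
    return ShrinkageLDA(pooling=pooling).fit(epochs.features, epochs.label)


def score_epochs(model, epochs: EpochSet) -> np.ndarray:
    """Per-epoch scores f(x) = wᵀx of any fitted decoder."""
    return model.decision_function(epochs.features)


def select_symbol(scores: np.ndarray, epochs: EpochSet, grid) -> int:
    """Arg-max symbol of per-symbol score sums over one trial's epochs.

    For each selectable (non-blank) grid symbol, the scores of all epochs
    whose stimulus highlighted it are summed; blanks are excluded from
    selection. Ties break toward the lowest symbol index.
    """
    scores = np.asarray(scores, dtype=float)
    if epochs.n_epochs == 0:
        raise ValueError("cannot select a symbol from an empty trial")
    if epochs.highlighted is None:
        raise ValueError("epochs carry no highlighted-symbol sets")
    if scores.shape != (epochs.n_epochs,):
        raise ValueError("need one score per epoch")
    sums = np.zeros(len(grid.symbols))
    for score, highlighted in zip(scores, epochs.highlighted):
        for s in highlighted:
            sums[s] += score
    selectable = grid.selectable_indices
    best = selectable[np.argmax(sums[selectable])]
    return int(best)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Target-vs-non-target ROC AUC; ties count 1/2 (Mann–Whitney).

    The probability that a uniformly random target epoch scores higher
    than a uniformly random non-target epoch; chance level 0.5.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos, neg = labels == TARGET, labels == NONTARGET
    if not (pos | neg).all():
        raise ValueError("labels must be +1 or -1")
    if not pos.any() or not neg.any():
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(pos.astype(int), scores))


# -- serialization: JSON metadata + binary array sidecar --------------------


def save_model(model, path: str | Path) -> None:
    """Write a fitted decoder to ``<path>.json`` + ``<path>.npz``."""
    path = Path(path)
    kind = type(model).__name__
    meta = {
        "kind": kind,
        "params": {
            k: (v.proportions.tolist() if isinstance(v, MixingMatrix) else v)
            for k, v in model.get_params().items()
        },
        "shrinkage": float(model.shrinkage_),
        "n_epochs": int(model.n_epochs_),
        "n_features": int(model.n_features_in_),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True))
    np.savez(
        path.with_suffix(".npz"),
        coef=model.coef_,
        target_mean=model.class_means_.target_mean,
        nontarget_mean=model.class_means_.nontarget_mean,
        covariance=model.covariance_,
    )


def load_model(path: str | Path):
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arrays = np.load(path.with_suffix(".npz"))
    cls = {"LLPDecoder": LLPDecoder, "ShrinkageLDA": ShrinkageLDA}[meta["kind"]]
    params = dict(meta["params"])
    if cls is LLPDecoder and params.get("mixing") is not None:
        params["mixing"] = MixingMatrix(np.asarray(params["mixing"]))
    model = cls(**params)
    model.coef_ = arrays["coef"]
    model.class_means_ = ClassMeans(
        target_mean=arrays["target_mean"], nontarget_mean=arrays["nontarget_mean"]
    )
    model.covariance_ = arrays["covariance"]
    model.shrinkage_ = meta["shrinkage"]
    model.n_epochs_ = meta["n_epochs"]
    model.n_features_in_ = meta["n_features"]
    return model
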