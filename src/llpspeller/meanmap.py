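"""Mean-map algebra for learning from label proportions (LLP).

The mean-map idea: if the data fall into G groups whose target/non-target
class proportions are known — the G×2 mixing matrix Π with rows
(π+g, π−g) — then the group mean feature vectors are linear mixtures of the
two class means,

    [μ1; ...; μG] = Π · [μ+; μ−],

and the class means can be recovered *without any per-sample labels* by
applying the (pseudo)inverse of Π to the empirical group means. The price
of unsupervision is variance inflation: each pseudoinverse coefficient ν
multiplies an independent group-mean estimate, so the class-mean estimation
variance grows with the sum of squared coefficients. The noise
amplification factor

    NAF = G · Σ_c Σ_k (ν_ck)²

quantifies how many times more data LLP needs than a supervised estimator
for the same mean-estimation accuracy (NAF = 4 for pure groups, i.e. the
supervised case with G = 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np

from .epochs import NONTARGET, TARGET, EpochSet

__all__ = [
    "MixingMatrix",
    "GroupMeans",
    "ClassMeans",
    "RankDeficientMixingError",
    "estimate_group_means",
    "reconstruct_class_means",
    "pseudoinverse_coefficients",
    "noise_amplification_factor",
    "squared_loss_label_term",
]

# Relative singular-value cutoff below which Π is treated as rank deficient.
RANK_TOL = 1e-10


class RankDeficientMixingError(ValueError):
    """Raised when the mixing matrix does not identify the two classes."""


def _parse_fraction(value) -> float:
    """Accept floats or exact-rational strings like '3/8'."""
    if isinstance(value, str):
        return float(Fraction(value))
    return float(value)


@dataclass(frozen=True)
class MixingMatrix:
    """G×2 table of per-group target and non-target proportions.

    Row g is (π+g, π−g): the fraction of target and non-target epochs in
    proportion group g. Rows must sum to one and the matrix must have rank
    2, otherwise the class means are not identifiable.
    """

    proportions: np.ndarray
    group_names: tuple = ()

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, dtype=float)
        if props.ndim != 2 or props.shape[1] != 2:
            raise ValueError("mixing matrix must be G x 2")
        if props.shape[0] < 2:
            raise ValueError("need at least G = 2 proportion groups")
        if np.any(props < 0) or np.any(props > 1):
            raise ValueError("proportions must lie in [0, 1]")
        if np.max(np.abs(props.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("each mixing row must sum to 1")
        object.__setattr__(self, "proportions", props)
        names = tuple(self.group_names) or tuple(range(1, props.shape[0] + 1))
        if len(names) != props.shape[0]:
            raise ValueError("need one group name per row")
        object.__setattr__(self, "group_names", names)
        sv = np.linalg.svd(props, compute_uv=False)
        if sv[-1] < RANK_TOL * sv[0]:
            raise RankDeficientMixingError(
                "mixing matrix is rank deficient (identical class proportions "
                "across groups): class means are not identifiable"
            )

    @property
    def n_groups(self) -> int:
        return self.proportions.shape[0]

    @classmethod
    def from_rows(cls, rows: Sequence[Sequence], group_names: Sequence = ()) -> "MixingMatrix":
        """Build from rows of floats or exact-rational strings ('3/8')."""
        props = [[_parse_fraction(v) for v in row] for row in rows]
        return cls(np.asarray(props), tuple(group_names))

    @classmethod
    def study_default(cls) -> "MixingMatrix":
        """The two-sequence speller mixing: rows (3/8, 5/8) and (2/18, 16/18)."""
        return cls.from_rows([["3/8", "5/8"], ["2/18", "16/18"]], group_names=(1, 2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MixingMatrix":
        """Read ``{"rows": [[...], ...], "group_names": [...]}`` from JSON."""
        spec = json.loads(Path(path).read_text())
        return cls.from_rows(spec["rows"], tuple(spec.get("group_names", ())))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rows": self.proportions.tolist(),
            "group_names": [str(n) for n in self.group_names]
            if any(isinstance(n, str) for n in self.group_names)
            else list(self.group_names),
        }
        Path(path).write_text(json.dumps(payload))


@dataclass(frozen=True)
class GroupMeans:
    """Empirical mean feature vector and epoch count of each group."""

    means: np.ndarray  # (G, D)
    counts: np.ndarray  # (G,)

    def __post_init__(self) -> None:
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (means.shape[0],):
            raise ValueError("need one count per group")
        if np.any(counts < 1):
            raise ValueError("every group needs at least one epoch")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class ClassMeans:
    """Reconstructed (or labelled) target and non-target mean vectors."""

    target_mean: np.ndarray
    nontarget_mean: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.target_mean, dtype=float).ravel()
        n = np.asarray(self.nontarget_mean, dtype=float).ravel()
        if t.shape != n.shape:
            raise ValueError("class means must have equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(n))):
            raise ValueError("class means must be finite")
        object.__setattr__(self, "target_mean", t)
        object.__setattr__(self, "nontarget_mean", n)

    @property
    def difference(self) -> np.ndarray:
        """μ+ − μ−, the direction the LDA projection is built from."""
        return self.target_mean - self.nontarget_mean


def estimate_group_means(
    epochs: EpochSet, group_order: Sequence | None = None
) -> GroupMeans:
    """Per-group arithmetic mean feature vectors and epoch counts.

    ``group_order`` fixes the row order (it must list every tag present);
    by default rows follow the sorted unique group tags.
    """
    tags = epochs.group
    if group_order is None:
        group_order = sorted(set(tags.tolist()))
    means, counts = [], []
    seen = set()
    for g in group_order:
        mask = tags == g
        k = int(mask.sum())
        if k == 0:
            raise ValueError(f"group {g!r} has no epochs")
        means.append(epochs.features[mask].mean(axis=0))
        counts.append(k)
        seen.add(g)
    missing = set(tags.tolist()) - seen
    if missing:
        raise ValueError(f"epochs carry group tags outside the schedule: {sorted(missing)!r}")
    return GroupMeans(means=np.asarray(means), counts=np.asarray(counts))


def pseudoinverse_coefficients(mixing: MixingMatrix) -> np.ndarray:
    """The 2×G coefficients ν mapping group means to class means.

    Equals (ΠᵀΠ)⁻¹Πᵀ; computed through an SVD-based pseudoinverse for
    numerical stability. Row 0 holds the target coefficients ν+, row 1 the
    non-target coefficients ν−.
    """
    return np.linalg.pinv(mixing.proportions, rcond=RANK_TOL)


def reconstruct_class_means(group_means: GroupMeans, mixing: MixingMatrix) -> ClassMeans:
    """Solve Π·[μ+; μ−] = [μ1 … μG] for the class means (least squares).

    For G = 2 this is the exact 2×2 inverse solution; for G > 2 it is the
    minimum-norm least-squares solution through the pseudoinverse.
    """
    if group_means.means.shape[0] != mixing.n_groups:
        raise ValueError(
            f"group means have {group_means.means.shape[0]} rows, "
            f"mixing matrix has {mixing.n_groups}"
        )
    coeffs = pseudoinverse_coefficients(mixing)
    solution = coeffs @ group_means.means
    return ClassMeans(target_mean=solution[0], nontarget_mean=solution[1])


def noise_amplification_factor(mixing: MixingMatrix) -> float:
    """G times the squared Frobenius norm of the mixing pseudoinverse.

    The factor by which LLP inflates class-mean estimation variance
    relative to a supervised estimator at the same total sample size, under
    IID equal-variance features split evenly across groups.
    """
    coeffs = pseudoinverse_coefficients(mixing)
    return float(mixing.n_groups * np.sum(coeffs**2))


def squared_loss_label_term(
    epochs: EpochSet, w: np.ndarray, method: str = "check"
) -> float:
    """Label-dependent term of the square loss: 2wᵀ(N+μ+ − N−μ−).

    Test-only identity behind the mean-map justification: the square loss
    splits into a label-free part and this term, which depends on the data
    only through class means and counts. ``method`` selects the route:
    'samples' sums per-sample (2wᵀ(Σx_i+ − Σx_i−)), 'means' uses class
    means and counts, 'check' computes both and verifies they agree to
    1e-9 relative before returning.
    """
    if epochs.label is None or np.any(epochs.label == 0):
        raise ValueError("squared_loss_label_term requires fully labelled epochs")
    w = np.asarray(w, dtype=float).ravel()
    pos = epochs.label == TARGET
    neg = epochs.label == NONTARGET

    def from_samples() -> float:
        return float(2.0 * w @ (epochs.features[pos].sum(axis=0) - epochs.features[neg].sum(axis=0)))

    def from_means() -> float:
        n_pos, n_neg = int(pos.sum()), int(neg.sum())
        mu_pos = epochs.features[pos].mean(axis=0) if n_pos else np.zeros_like(w)
        mu_neg = epochs.features[neg].mean(axis=0) if n_neg else np.zeros_like(w)
        return float(2.0 * w @ (n_pos * mu_pos - n_neg * mu_neg))

    if method == "samples":
        return from_samples()
    if method == "means":
        return from_means()
    if method == "check":
        a, b = from_samples(), from_means()
        scale = max(abs(a), abs(b), 1e-300)
        if abs(a - b) > 1e-9 * scale:
            raise AssertionError("loss-term identity violated beyond tolerance")
        return a
    raise ValueError(f"unknown method {method!r}")
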