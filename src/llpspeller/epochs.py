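"""The EpochSet container: one row per stimulus epoch.

An epoch is the basic classification sample of an ERP interface: the feature
vector extracted from the EEG around one highlighting event, together with
the metadata the unsupervised decoder and the evaluation harness need —
which proportion group (stimulus sequence) the epoch came from, which trial
(character selection) it belongs to, which grid symbols were highlighted,
and (for evaluation only) its true target/non-target label.

Labels use the convention +1 = target, -1 = non-target, 0 = unknown.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = ["EpochSet", "TARGET", "NONTARGET", "UNKNOWN"]

TARGET = 1
NONTARGET = -1
UNKNOWN = 0


@dataclass
class EpochSet:
    """N epochs with a D-dimensional feature vector and per-epoch metadata.

    Parameters
    ----------
    features : (N, D) float array
        One feature vector per epoch; must be finite.
    group : (N,) array
        Proportion-group tag of each epoch (e.g. sequence id 1 or 2).
    trial : (N,) int array, optional
        Trial (character) index of each epoch, chronological.
    highlighted : sequence of N frozensets of int, optional
        Grid-symbol indices highlighted in the epoch's stimulus event.
    label : (N,) int array, optional
        +1 target / -1 non-target / 0 unknown. Evaluation only: no training
        code path of the LLP decoder may read this field.
    """

    features: np.ndarray
    group: np.ndarray
    trial: np.ndarray | None = None
    highlighted: list[frozenset[int]] | None = None
    label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D (N, D) array")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        n = self.features.shape[0]
        self.group = np.asarray(self.group)
        if self.group.shape != (n,):
            raise ValueError("group must have one tag per epoch")
        if self.trial is not None:
            self.trial = np.asarray(self.trial, dtype=int)
            if self.trial.shape != (n,):
                raise ValueError("trial must have one id per epoch")
        if self.highlighted is not None:
            self.highlighted = [frozenset(h) for h in self.highlighted]
            if len(self.highlighted) != n:
                raise ValueError("highlighted must have one set per epoch")
        if self.label is not None:
            self.label = np.asarray(self.label, dtype=int)
            if self.label.shape != (n,):
                raise ValueError("label must have one entry per epoch")
            bad = ~np.isin(self.label, (TARGET, NONTARGET, UNKNOWN))
            if bad.any():
                raise ValueError("labels must be +1, -1 or 0")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_epochs(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def is_labelled(self) -> bool:
        return self.label is not None and bool(np.all(self.label != UNKNOWN))

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset by boolean mask or index array, keeping all metadata."""
        idx = np.arange(self.n_epochs)[mask]
        return EpochSet(
            features=self.features[idx],
            group=self.group[idx],
            trial=None if self.trial is None else self.trial[idx],
            highlighted=None
            if self.highlighted is None
            else [self.highlighted[i] for i in idx],
            label=None if self.label is None else self.label[idx],
        )

    def without_labels(self) -> "EpochSet":
        """A copy with the label column dropped (unsupervised view)."""
        return EpochSet(
            features=self.features.copy(),
            group=self.group.copy(),
            trial=None if self.trial is None else self.trial.copy(),
            highlighted=None if self.highlighted is None else list(self.highlighted),
            label=None,
        )

    @classmethod
    def concat(cls, parts: Iterable["EpochSet"]) -> "EpochSet":
        parts = list(parts)
        if not parts:
            raise ValueError("nothing to concatenate")

        def _cat(attr: str):
            vals = [getattr(p, attr) for p in parts]
            if any(v is None for v in vals):
                return None
            if attr == "highlighted":
                return [h for v in vals for h in v]
            return np.concatenate(vals)

        return cls(
            features=np.vstack([p.features for p in parts]),
            group=np.concatenate([p.group for p in parts]),
            trial=_cat("trial"),
            highlighted=_cat("highlighted"),
            label=_cat("label"),
        )

    # -- persistence: tabular numeric file + JSON metadata sidecar ---------

    def save(self, prefix: str | Path) -> None:
        """Write features as ``<prefix>.features.csv`` and metadata as
        ``<prefix>.meta.json``."""
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".features.csv"), self.features, delimiter=",")
        meta = {
            "group": [_jsonable(g) for g in self.group.tolist()],
            "trial": None if self.trial is None else self.trial.tolist(),
            "highlighted": None
            if self.highlighted is None
            else [sorted(h) for h in self.highlighted],
            "label": None if self.label is None else self.label.tolist(),
        }
        prefix.with_suffix(".meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, prefix: str | Path) -> "EpochSet":
        prefix = Path(prefix)
        features = np.loadtxt(prefix.with_suffix(".features.csv"), delimiter=",", ndmin=2)
        meta = json.loads(prefix.with_suffix(".meta.json").read_text())
        return cls(
            features=features,
            group=np.asarray(meta["group"]),
            trial=meta["trial"],
            highlighted=None
            if meta["highlighted"] is None
            else [frozenset(h) for h in meta["highlighted"]],
            label=meta["label"],
        )


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value
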