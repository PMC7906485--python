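"""Core data containers for N-way biclustering.

A *bicluster* is a (subject subset, feature subset) pair whose submatrix of
loading values is homogeneously high. The search operates on a labelled
subjects x features loading matrix (for example ICA loading parameters from
source-based morphometry, optionally concatenated with symptom scores).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LoadingMatrix",
    "SymptomTable",
    "SearchConfig",
    "ThresholdPair",
    "Bicluster",
    "GroundTruthSet",
]

#: allowed per-column kinds of a loading matrix
FEATURE_KINDS = ("imaging", "symptom")


@dataclass(frozen=True)
class LoadingMatrix:
    """A subjects x features matrix of real loading values with labels.

    Parameters
    ----------
    values
        Array of shape ``(n_subjects, n_features)``; every entry finite.
    subject_ids
        Ordered, unique subject identifiers (opaque hashables).
    feature_labels
        Ordered, unique feature labels (opaque hashables).
    feature_kinds
        Per-column kind, one of ``"imaging"`` or ``"symptom"``. Defaults to
        all-imaging.
    """

    values: np.ndarray
    subject_ids: tuple
    feature_labels: tuple
    feature_kinds: tuple = ()

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "feature_labels", tuple(self.feature_labels))
        kinds = tuple(self.feature_kinds) or ("imaging",) * values.shape[1]
        object.__setattr__(self, "feature_kinds", kinds)
        if values.ndim != 2:
            raise ValueError("loading values must be a 2-D matrix")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite loading at subject index {bad[0]}, feature index {bad[1]}"
            )
        n, m = values.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match row count")
        if len(self.feature_labels) != m:
            raise ValueError("feature_labels length does not match column count")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject identifiers")
        if len(set(self.feature_labels)) != m:
            raise ValueError("duplicate feature labels")
        if len(kinds) != m:
            raise ValueError("feature_kinds length does not match column count")
        for k in kinds:
            if k not in FEATURE_KINDS:
                raise ValueError(f"unknown feature kind {k!r}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def imaging_labels(self) -> tuple:
        return tuple(
            lab
            for lab, kind in zip(self.feature_labels, self.feature_kinds)
            if kind == "imaging"
        )

    @property
    def symptom_labels(self) -> tuple:
        return tuple(
            lab
            for lab, kind in zip(self.feature_labels, self.feature_kinds)
            if kind == "symptom"
        )

    def column(self, label: Hashable) -> np.ndarray:
        """Loading values of one feature, in subject order."""
        return self.values[:, self.feature_labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.subject_ids), columns=list(self.feature_labels)
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, symptom_columns: Iterable[Hashable] = ()
    ) -> "LoadingMatrix":
        symptom = set(symptom_columns)
        unknown = symptom - set(frame.columns)
        if unknown:
            raise ValueError(f"symptom columns not present in matrix: {sorted(map(str, unknown))}")
        kinds = tuple("symptom" if c in symptom else "imaging" for c in frame.columns)
        return cls(
            values=frame.to_numpy(dtype=float),
            subject_ids=tuple(frame.index),
            feature_labels=tuple(frame.columns),
            feature_kinds=kinds,
        )

    def zscored(self) -> "LoadingMatrix":
        """Per-column z-scored copy (population SD; constant columns left at 0).

        Puts questionnaire-scale symptom scores and unit-free ICA loadings on
        comparable footing before sorting, since the sorting rules compare
        values against column means.
        """
        v = self.values
        mu = v.mean(axis=0)
        sd = v.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return replace(self, values=(v - mu) / sd)


@dataclass(frozen=True)
class SymptomTable:
    """Subjects x symptom-score table (questionnaire-scale units, e.g. PANSS)."""

    values: np.ndarray
    subject_ids: tuple
    score_labels: tuple

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "score_labels", tuple(self.score_labels))
        if values.ndim != 2:
            raise ValueError("symptom values must be a 2-D matrix")
        if len(self.subject_ids) != values.shape[0]:
            raise ValueError("subject_ids length does not match row count")
        if len(self.score_labels) != values.shape[1]:
            raise ValueError("score_labels length does not match column count")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject identifiers")
        if len(set(self.score_labels)) != len(self.score_labels):
            raise ValueError("duplicate score labels")

    def score(self, label: Hashable) -> np.ndarray:
        return self.values[:, self.score_labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.subject_ids), columns=list(self.score_labels)
        )

    @classmethod
    def from_loading_matrix(cls, matrix: LoadingMatrix) -> "SymptomTable":
        """Extract the symptom-kind columns of a loading matrix as a score table."""
        labels = matrix.symptom_labels
        if not labels:
            raise ValueError("loading matrix has no symptom columns")
        cols = [matrix.feature_labels.index(lab) for lab in labels]
        return cls(matrix.values[:, cols], matrix.subject_ids, labels)


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of the exhaustive bicluster search.

    N : minimum subjects per bicluster.
    K : minimum features per bicluster.
    O : allowed overlap percentage between biclusters, in [0, 100].
    OE : optional cross-permutation overlap percentage; defaults to O.
    M : sorting-method selector, 1-4 (4, extreme positive-or-negative, default).
    permutation_budget : maximum number of feature-order permutations evaluated.
    seed : RNG seed for permutation sampling.
    min_frequency : minimum stability frequency retained in the final report.
    """

    N: int = 1
    K: int = 2
    O: float = 35.0
    OE: float | None = None
    M: int = 4
    permutation_budget: int = 720
    seed: int = 0
    min_frequency: int = 2

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if not 0 <= self.O <= 100:
            raise ValueError("O must be in [0, 100]")
        if self.OE is not None and not 0 <= self.OE <= 100:
            raise ValueError("OE must be in [0, 100]")
        if self.M not in (1, 2, 3, 4):
            raise ValueError("M must be one of 1, 2, 3, 4")
        if self.permutation_budget < 1:
            raise ValueError("permutation_budget must be >= 1")
        if self.min_frequency < 1:
            raise ValueError("min_frequency must be >= 1")


@dataclass(frozen=True)
class ThresholdPair:
    """F1-similarity thresholds derived from the overlap percentages.

    ``fth1`` gates overlap between biclusters discovered within one
    permutation; ``fth2`` gates overlap against biclusters from earlier
    permutations (the global stability check).
    """

    fth1: float
    fth2: float

    def __post_init__(self):
        if not (0 <= self.fth1 <= 1 and 0 <= self.fth2 <= 1):
            raise ValueError("thresholds must be in [0, 1]")


@dataclass(frozen=True)
class Bicluster:
    """A (subject subset, feature subset) pair with a stability frequency.

    ``frequency`` counts in how many permutation orders this bicluster (or an
    overlap-equivalent one) was rediscovered.
    """

    subject_set: frozenset
    feature_set: frozenset
    frequency: int = 1

    def __post_init__(self):
        object.__setattr__(self, "subject_set", frozenset(self.subject_set))
        object.__setattr__(self, "feature_set", frozenset(self.feature_set))
        if not self.subject_set:
            raise ValueError("bicluster subject set is empty")
        if not self.feature_set:
            raise ValueError("bicluster feature set is empty")
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_set)

    @property
    def n_features(self) -> int:
        return len(self.feature_set)

    @property
    def size(self) -> int:
        """Cell count |S| x |F| of the induced submatrix."""
        return len(self.subject_set) * len(self.feature_set)

    def submatrix(self, matrix: LoadingMatrix) -> np.ndarray:
        """Extract this bicluster's submatrix from a loading matrix."""
        rows = [matrix.subject_ids.index(s) for s in sorted(self.subject_set, key=str)]
        cols = [matrix.feature_labels.index(f) for f in sorted(self.feature_set, key=str)]
        return matrix.values[np.ix_(rows, cols)]


@dataclass(frozen=True)
class GroundTruthSet:
    """Planted (subject set, feature set) blocks used by simulation fixtures."""

    blocks: tuple

    def __post_init__(self):
        object.__setattr__(
            self,
            "blocks",
            tuple(
                (frozenset(subjects), frozenset(features))
                for subjects, features in self.blocks
            ),
        )
        for subjects, features in self.blocks:
            if not subjects or not features:
                raise ValueError("ground-truth block with empty subject or feature set")

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def as_biclusters(self) -> list:
        return [Bicluster(s, f) for s, f in self.blocks]

    def check_bounds(self, matrix: LoadingMatrix) -> None:
        subjects = set(matrix.subject_ids)
        features = set(matrix.feature_labels)
        for s, f in self.blocks:
            if not s <= subjects:
                raise ValueError("planted subjects outside the matrix")
            if not f <= features:
                raise ValueError("planted features outside the matrix")
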