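"""Feature sorting: reduce each feature column to its high-loading subjects.

Each feature of the loading matrix is converted into a *sorted component*
(SCOMP): the subset of subjects whose loading on that feature is extreme
under one of four rules. SCOMPs are the atomic sets intersected by the
bicluster search.

Method 1 (positive and negative)
    Take the mean of the strictly positive loadings and the mean of the
    strictly negative loadings separately; keep subjects with loading >=
    the positive mean or <= the negative mean.
Method 2 (positive and negative quartiles)
    Keep the upper quartile of the positive loadings and the lower quartile
    of the negative loadings (linear-interpolation percentiles over each
    subsample, closed boundaries).
Method 3 (absolute value)
    Keep subjects with |loading| >= |mean loading| of the column.
Method 4 (positive or negative, the default)
    If the column mean is nonnegative, keep loadings >= the mean
    (extremely positive); otherwise keep loadings < the mean (extremely
    negative).

Zero loadings count as neither positive nor negative for methods 1-2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import LoadingMatrix

__all__ = ["SortedComponent", "sort_component", "sort_all"]


@dataclass(frozen=True)
class SortedComponent:
    """One feature's selected high-loading subject subset."""

    feature_label: object
    subject_set: frozenset

    def __post_init__(self):
        object.__setattr__(self, "subject_set", frozenset(self.subject_set))


def sort_component(column: np.ndarray, method: int = 4) -> frozenset:
    """Select the extreme-loading subject *indices* of one feature column.

    Parameters
    ----------
    column
        Finite 1-D array of loading values, one per subject.
    method
        Sorting rule 1-4 (see module docstring).

    Returns
    -------
    frozenset of 0-based subject indices.
    """
    x = np.asarray(column, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("column must be a nonempty 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("column contains non-finite values")
    idx = np.arange(x.size)
    # closed comparisons get a tiny tolerance so that a constant column is
    # not split by round-off in its own mean
    eps = 1e-12

    if method == 1:
        pos, neg = x[x > 0], x[x < 0]
        selected = np.zeros(x.size, dtype=bool)
        if pos.size:
            selected |= x >= pos.mean() - eps
        if neg.size:
            selected |= x <= neg.mean() + eps
        return frozenset(idx[selected])
    if method == 2:
        pos, neg = x[x > 0], x[x < 0]
        selected = np.zeros(x.size, dtype=bool)
        if pos.size:
            selected |= x >= np.percentile(pos, 75) - eps
        if neg.size:
            selected |= (x < 0) & (x <= np.percentile(neg, 25) + eps)
        return frozenset(idx[selected])
    if method == 3:
        return frozenset(idx[np.abs(x) >= abs(x.mean()) - eps])
    if method == 4:
        mu = x.mean()
        if mu >= 0:
            return frozenset(idx[x >= mu - eps])
        return frozenset(idx[x < mu - eps])
    raise ValueError(f"unknown sorting method {method!r}")


def sort_all(matrix: LoadingMatrix, method: int = 4) -> list[SortedComponent]:
    """Sort every feature of a loading matrix, in column order.

    Returns one :class:`SortedComponent` per feature; membership is expressed
    in subject identifiers. Feature IDs used downstream are the 1-based
    column positions of this list.
    """
    scomps = []
    for j, label in enumerate(matrix.feature_labels):
        try:
            indices = sort_component(matrix.values[:, j], method)
        except ValueError as exc:
            raise ValueError(f"feature {label!r}: {exc}") from exc
        subjects = frozenset(matrix.subject_ids[i] for i in indices)
        scomps.append(SortedComponent(label, subjects))
    return scomps
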