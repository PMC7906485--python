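"""Synthetic loading-matrix generators with planted biclusters.

The generators emulate an ICA-loading matrix: each feature column is drawn
from a normal distribution with its own mean, truncated to [-1, 1]. Planted
biclusters are embedded by raising the loading values of the planted cells
so that every planted cell stays above the *positive mean* of its column
(by a small margin), which makes each planted subject eligible for that
column's sorted component and turns the planted blocks into intrinsic
biclusters of the matrix.

Two fixed designs are provided:

* ``simulation1_fixture`` — 400 subjects x 10 features with four planted
  blocks of 38/35/37/40 subjects x 3 features each, used to compare the
  sorting rules.
* ``simulation2_fixture`` — 40 subjects x 10 features with three planted
  blocks of 13 subjects x 3 features, with mutually disjoint subject sets;
  a small end-to-end demonstration of the search.

``generate_symptom_coupled`` additionally appends questionnaire-style
symptom columns (PANSS-like range 7-49) whose values correlate with
membership in chosen planted blocks, for exercising the association stage.
"""

from __future__ import annotations

import numpy as np

from .types import GroundTruthSet, LoadingMatrix

__all__ = [
    "SIM1_BLOCKS",
    "SIM2_BLOCKS",
    "generate_base_matrix",
    "embed_biclusters",
    "simulation1_fixture",
    "simulation2_fixture",
    "generate_symptom_coupled",
]

# Planted memberships of the 400 x 10 design (1-based subject / feature IDs).
SIM1_BLOCKS = (
    (
        (278, 342, 118, 261, 12, 378, 313, 331, 295, 318, 163, 53, 64, 327,
         133, 218, 330, 380, 185, 28, 209, 79, 120, 391, 67, 311, 137, 190,
         41, 25, 345, 29, 354, 158, 177, 141, 13, 291),
        (2, 9, 3),
    ),
    (
        (271, 195, 325, 31, 12, 174, 58, 324, 1, 39, 169, 95, 383, 149, 197,
         108, 231, 209, 392, 265, 339, 35, 170, 17, 241, 293, 274, 25, 27,
         123, 140, 291, 43, 101, 176),
        (1, 4, 5),
    ),
    (
        (125, 367, 264, 71, 259, 15, 314, 1, 154, 269, 16, 174, 70, 234, 77,
         145, 353, 10, 273, 114, 329, 118, 157, 381, 335, 357, 374, 52, 140,
         286, 251, 334, 89, 128, 88, 12, 237),
        (6, 7, 8),
    ),
    (
        (46, 29, 233, 5, 338, 27, 194, 65, 169, 346, 263, 385, 159, 165, 312,
         361, 268, 69, 128, 109, 93, 281, 124, 390, 345, 248, 352, 123, 251,
         254, 121, 234, 44, 320, 351, 260, 23, 376, 24, 100),
        (2, 4, 6),
    ),
)

# Planted memberships of the 40 x 10 design: three disjoint 13-subject blocks.
SIM2_BLOCKS = (
    ((1, 2, 3, 4, 6, 7, 21, 27, 29, 31, 35, 38, 40), (1, 8, 3)),
    ((5, 13, 17, 18, 19, 20, 23, 24, 26, 28, 30, 33, 34), (2, 4, 5)),
    ((8, 9, 10, 11, 12, 14, 15, 16, 22, 25, 32, 36, 39), (6, 7, 9)),
)


def generate_base_matrix(
    n_subjects: int,
    n_features: int,
    seed: int,
    mean_range: float = 0.3,
    sd: float = 0.3,
) -> LoadingMatrix:
    """Background loading matrix: per-column truncated normal columns.

    Each column j gets a mean drawn uniformly from (-mean_range, mean_range)
    and SD ``sd``; values are clipped to [-1, 1]. Subject IDs and feature
    labels are the 1-based integers. Deterministic per seed.
    """
    if n_subjects < 1 or n_features < 1:
        raise ValueError("matrix dimensions must be positive")
    rng = np.random.default_rng(seed)
    col_means = rng.uniform(-mean_range, mean_range, size=n_features)
    values = rng.normal(loc=col_means, scale=sd, size=(n_subjects, n_features))
    values = np.clip(values, -1.0, 1.0)
    return LoadingMatrix(
        values=values,
        subject_ids=tuple(range(1, n_subjects + 1)),
        feature_labels=tuple(range(1, n_features + 1)),
    )


def embed_biclusters(
    matrix: LoadingMatrix,
    truth: GroundTruthSet,
    seed: int,
    low: float = 0.8,
    high: float = 1.0,
    margin: float = 0.05,
) -> LoadingMatrix:
    """Raise planted cells so each exceeds its column's positive mean.

    Planted cells are drawn uniformly from [low, high]; afterwards every
    planted cell is checked against mu+_j + margin, where mu+_j is the
    *post-embedding* mean over the strictly positive entries of column j.
    Violating cells are re-drawn from [mu+_j + margin, 1]. Because raising
    cells also raises mu+_j, the repair iterates (the floor is monotone
    increasing, so it either stabilizes or runs out of headroom below 1).
    When the planted cells dominate the column's positive entries no
    strict-margin fixed point exists (the minimum of a set cannot exceed
    its own mean); such columns fall back to one common planted value at
    or above the background positive mean, which satisfies the closed
    (>=) selection inequalities exactly.

    The guarantee makes every planted subject eligible for the column's
    sorted component under the positive-mean rule (method 1) and the
    absolute-value rule (method 3); the positive-or-negative rule (method 4)
    also selects all planted subjects whenever the column's overall
    post-embedding mean is nonnegative.
    """
    truth.check_bounds(matrix)
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    s_index = {s: i for i, s in enumerate(matrix.subject_ids)}
    f_index = {f: j for j, f in enumerate(matrix.feature_labels)}

    planted: dict[int, list[int]] = {}
    for subjects, features in truth:
        for f in features:
            j = f_index[f]
            rows = planted.setdefault(j, [])
            rows.extend(s_index[s] for s in subjects)
    planted = {j: sorted(set(rows)) for j, rows in planted.items()}

    for j, rows in planted.items():
        values[rows, j] = rng.uniform(low, high, size=len(rows))

    # repair against the post-embedding positive mean until stable
    for j, rows in planted.items():
        stable = False
        for _ in range(100):
            col = values[:, j]
            pos_mean = col[col > 0].mean()
            floor = pos_mean + margin
            if floor > 1.0:
                break
            violators = [i for i in rows if values[i, j] < floor]
            if not violators:
                stable = True
                break
            values[violators, j] = rng.uniform(floor, 1.0, size=len(violators))
        if stable:
            continue
        # the strict-margin fixed point does not exist when the planted
        # cells dominate the column's positive entries; a common planted
        # value >= the background positive mean then *equals or exceeds*
        # the overall positive mean, satisfying the closed (>=) selection
        # inequalities with zero margin
        other = np.delete(values[:, j], rows)
        pos_bg = other[other > 0]
        v = (low + high) / 2.0
        if pos_bg.size:
            v = min(1.0, max(v, float(pos_bg.mean()) + margin))
        values[rows, j] = v
        col = values[:, j]
        if not np.all(values[rows, j] >= col[col > 0].mean() - 1e-12):
            raise ValueError(
                f"column {matrix.feature_labels[j]!r}: cannot place planted "
                "cells at or above the column's positive mean"
            )

    return LoadingMatrix(
        values=values,
        subject_ids=matrix.subject_ids,
        feature_labels=matrix.feature_labels,
        feature_kinds=matrix.feature_kinds,
    )


def simulation1_fixture(seed: int) -> tuple[LoadingMatrix, GroundTruthSet]:
    """400 x 10 loading matrix with the four fixed planted blocks."""
    truth = GroundTruthSet(SIM1_BLOCKS)
    base = generate_base_matrix(400, 10, seed)
    return embed_biclusters(base, truth, seed + 1), truth


def simulation2_fixture(seed: int) -> tuple[LoadingMatrix, GroundTruthSet]:
    """40 x 10 loading matrix with the three fixed disjoint planted blocks."""
    truth = GroundTruthSet(SIM2_BLOCKS)
    base = generate_base_matrix(40, 10, seed)
    return embed_biclusters(base, truth, seed + 1), truth


def generate_symptom_coupled(
    n_subjects: int,
    n_imaging: int,
    n_symptoms: int,
    coupling: float,
    truth: GroundTruthSet,
    seed: int,
) -> tuple[LoadingMatrix, GroundTruthSet]:
    """Imaging matrix with planted blocks plus block-coupled symptom columns.

    Symptom column k is a linear combination of the standardized membership
    indicator of planted block ``k mod len(truth)`` (weight ``coupling``)
    and independent Gaussian noise (weight ``sqrt(1 - coupling^2)``), mapped
    affinely to a PANSS-like scale with mean 28 and SD 7 and clipped to
    [7, 49]. At coupling 0 the scores are independent of block membership;
    at coupling c the population correlation between membership and score is
    approximately c. Symptom columns are labelled ``positive``, ``negative``,
    ``general`` when ``n_symptoms == 3``, else ``sym1``.. and are flagged
    with feature kind ``"symptom"``.
    """
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must be in [0, 1]")
    if len(truth) == 0:
        raise ValueError("ground-truth set is empty")
    base = generate_base_matrix(n_subjects, n_imaging, seed)
    matrix = embed_biclusters(base, truth, seed + 1)
    rng = np.random.default_rng(seed + 2)

    labels = (
        ("positive", "negative", "general")
        if n_symptoms == 3
        else tuple(f"sym{k + 1}" for k in range(n_symptoms))
    )
    blocks = list(truth)
    sym = np.empty((n_subjects, n_symptoms))
    for k in range(n_symptoms):
        subjects, _ = blocks[k % len(blocks)]
        ind = np.array([1.0 if s in subjects else 0.0 for s in matrix.subject_ids])
        ind_sd = ind.std()
        ind_std = (ind - ind.mean()) / ind_sd if ind_sd > 0 else ind * 0.0
        z = coupling * ind_std + np.sqrt(1.0 - coupling**2) * rng.normal(size=n_subjects)
        sym[:, k] = np.clip(28.0 + 7.0 * z, 7.0, 49.0)

    values = np.hstack([matrix.values, sym])
    out = LoadingMatrix(
        values=values,
        subject_ids=matrix.subject_ids,
        feature_labels=matrix.feature_labels + labels,
        feature_kinds=("imaging",) * n_imaging + ("symptom",) * n_symptoms,
    )
    return out, truth
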