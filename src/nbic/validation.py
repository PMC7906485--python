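"""Overlap thresholds and the stability validators.

Bicluster similarity is the F1 (dice) index over matrix *cells*: for
biclusters A and B,

    F1(A, B) = 2 |A n B| / (|A| + |B|)

where |A| = |S_A| x |F_A| is A's cell count and |A n B| = (shared subjects)
x (shared features). Two thresholds derived from the allowed overlap
percentage O (and optionally OE) gate this similarity:

* ``fth1`` = O/100 — the *local* validator rejects a candidate that has
  F1 >= fth1 with any bicluster already accepted in the same permutation;
* ``fth2`` = (OE or O)/100 — the *global* stability checker merges a
  bicluster with F1 >= fth2 to an earlier one by incrementing that
  incumbent's frequency, rather than adding a near-duplicate.

These are the minimum thresholds implied by the size gates; "too similar"
is read as F1 >= threshold.
"""

from __future__ import annotations

from .types import Bicluster, ThresholdPair

__all__ = [
    "compute_thresholds",
    "f1_index",
    "local_validate",
    "global_update",
    "stability_filter",
]


def compute_thresholds(
    N: int, K: int, O: float, OE: float | None = None
) -> ThresholdPair:
    """Derive (fth1, fth2) from the overlap percentages O and OE.

    N and K are accepted for interface completeness: the simplified threshold
    depends only on the overlap percentage.
    """
    if not 0 <= O <= 100:
        raise ValueError("O must be in [0, 100]")
    if OE is not None and not 0 <= OE <= 100:
        raise ValueError("OE must be in [0, 100]")
    return ThresholdPair(fth1=O / 100.0, fth2=(O if OE is None else OE) / 100.0)


def f1_index(a: Bicluster, b: Bicluster) -> float:
    """Dice similarity of two biclusters over their matrix cells, in [0, 1]."""
    shared = len(a.subject_set & b.subject_set) * len(a.feature_set & b.feature_set)
    return 2.0 * shared / (a.size + b.size)


def local_validate(
    candidate: Bicluster, accepted: list[Bicluster], fth1: float
) -> bool:
    """Accept a candidate iff it is not fth1-similar to any accepted bicluster.

    First-come-first-kept: the earlier discovery in the permutation's
    depth-first order wins; a too-similar later candidate is discarded.
    """
    return all(f1_index(candidate, b) < fth1 for b in accepted)


def global_update(
    final_list: list[Bicluster], temp_list: list[Bicluster], fth2: float
) -> list[Bicluster]:
    """Fold one permutation's biclusters into the cross-permutation list.

    Each temporary bicluster either increments the frequency of the most
    similar incumbent (max F1 >= fth2; earliest incumbent wins ties, and its
    membership is kept unchanged) or is appended with frequency 1. Returns
    the updated list (mutated in place and returned).
    """
    for t in temp_list:
        best_i, best_f1 = -1, -1.0
        for i, b in enumerate(final_list):
            s = f1_index(t, b)
            if s > best_f1:
                best_i, best_f1 = i, s
        if best_i >= 0 and best_f1 >= fth2:
            incumbent = final_list[best_i]
            final_list[best_i] = Bicluster(
                incumbent.subject_set,
                incumbent.feature_set,
                incumbent.frequency + 1,
            )
        else:
            final_list.append(Bicluster(t.subject_set, t.feature_set, 1))
    return final_list


def stability_filter(
    final_list: list[Bicluster], min_frequency: int = 2
) -> list[Bicluster]:
    """Keep biclusters rediscovered at least ``min_frequency`` times.

    Sorted by frequency descending, then cell count descending; ties keep
    discovery order (stable sort), so the result is deterministic.
    """
    kept = [b for b in final_list if b.frequency >= min_frequency]
    return sorted(kept, key=lambda b: (-b.frequency, -b.size))
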