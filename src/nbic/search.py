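"""The permuter + Search_BiC engine.

Features are first reduced to sorted components (SCOMPs) and labelled with
1-based IDs by column position. For each permutation of the IDs the engine
enumerates every feature-ID subset of size >= K by depth-first
prefix-extension, intersects the corresponding SCOMP subject sets, and
keeps size-qualified candidates (>= N subjects, >= K features) that survive
the local overlap validator. Across permutations the global stability
checker folds each permutation's biclusters into a final list, counting
how many permutation orders rediscover each one (its *frequency*).

Subset intersections depend only on the subset, not on the permutation, so
they are memoized across permutations; permutations differ only in the
depth-first discovery order, which is exactly what the stability frequency
measures. Intersection is monotone (a superset of features can only shrink
the subject intersection), so branches whose running intersection already
falls below N are pruned without loss.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Iterator, Sequence

import numpy as np

from .sorting import SortedComponent, sort_all
from .types import Bicluster, LoadingMatrix, SearchConfig, ThresholdPair
from .validation import compute_thresholds, global_update, local_validate, stability_filter

__all__ = [
    "enumerate_subsets",
    "intersect_scomps",
    "search_bic",
    "sample_permutations",
    "run_nbic",
]

logger = logging.getLogger(__name__)


def enumerate_subsets(ids: Sequence, K: int) -> Iterator[tuple]:
    """Yield every subset of ``ids`` of size >= K, each exactly once.

    Order is depth-first prefix extension following the given sequence:
    each subset is yielded as a tuple in sequence order, and a subset is
    followed by its extensions before its siblings. For ids (1, 2, 3) and
    K=2: (1,2), (1,2,3), (1,3), (2,3).
    """
    if not ids:
        raise ValueError("ids must be nonempty")
    if K < 1:
        raise ValueError("K must be >= 1")
    n = len(ids)

    def extend(prefix: list, start: int) -> Iterator[tuple]:
        for i in range(start, n):
            prefix.append(ids[i])
            if len(prefix) >= K:
                yield tuple(prefix)
            yield from extend(prefix, i + 1)
            prefix.pop()

    yield from extend([], 0)


def intersect_scomps(
    scomps: dict, feature_subset: Iterable
) -> frozenset:
    """Exact intersection of the SCOMP subject sets of ``feature_subset``.

    ``scomps`` maps feature ID -> frozenset of subjects. Order-independent.
    """
    subset = list(feature_subset)
    if not subset:
        raise ValueError("feature subset must be nonempty")
    try:
        sets = [scomps[f] for f in subset]
    except KeyError as exc:
        raise KeyError(f"unknown feature ID {exc.args[0]!r}") from exc
    return frozenset(frozenset.intersection(*sets))


def _scomp_map(scomps: Sequence[SortedComponent]) -> dict:
    """Assign 1-based IDs by position and return {id: subject frozenset}."""
    return {i + 1: frozenset(sc.subject_set) for i, sc in enumerate(scomps)}


def search_bic(
    perm: Sequence,
    scomps: dict,
    config: SearchConfig,
    thresholds: ThresholdPair | None = None,
    _cache: dict | None = None,
) -> list[Bicluster]:
    """Run one permutation: DFS subset enumeration + local validation.

    Parameters
    ----------
    perm
        An ordering of the feature IDs (a bijection on ``scomps`` keys).
    scomps
        Mapping feature ID -> SCOMP subject frozenset.
    config
        Size gates N, K (other fields unused here).
    thresholds
        F1 thresholds; ``fth1`` gates within-permutation overlap.
    _cache
        Optional subset -> intersection memo shared across permutations.

    Returns
    -------
    The permutation's temporary bicluster list, in discovery order, each
    with frequency 1. Every returned bicluster's subject set equals the
    exact intersection of its features' SCOMPs.
    """
    if len(perm) != len(scomps) or set(perm) != set(scomps):
        raise ValueError("permutation is not a bijection on the feature IDs")
    if thresholds is None:
        thresholds = compute_thresholds(config.N, config.K, config.O, config.OE)
    cache = _cache if _cache is not None else {}
    accepted: list[Bicluster] = []
    n_ids = len(perm)

    def descend(prefix: list, start: int, subjects: frozenset) -> None:
        for i in range(start, n_ids):
            fid = perm[i]
            key = frozenset(prefix) | {fid}
            inter = cache.get(key)
            if inter is None:
                inter = subjects & scomps[fid] if prefix else scomps[fid]
                cache[key] = inter
            if len(inter) < config.N:
                continue  # monotone: no extension can recover >= N subjects
            prefix.append(fid)
            if len(prefix) >= config.K:
                candidate = Bicluster(inter, frozenset(prefix))
                if local_validate(candidate, accepted, thresholds.fth1):
                    accepted.append(candidate)
            descend(prefix, i + 1, inter)
            prefix.pop()

    all_subjects = frozenset().union(*scomps.values()) if scomps else frozenset()
    descend([], 0, all_subjects)
    return accepted


def sample_permutations(
    ids: Sequence, budget: int, seed: int
) -> list[tuple]:
    """All permutations of ``ids`` if there are at most ``budget``; otherwise
    a seeded uniform sample of ``budget`` distinct permutations, the first
    always being the identity order."""
    ids = tuple(ids)
    m = len(ids)
    total = math.factorial(m)
    if total <= budget:
        import itertools

        return list(itertools.permutations(ids))
    rng = np.random.default_rng(seed)
    perms = [ids]
    seen = {ids}
    while len(perms) < budget:
        p = tuple(ids[i] for i in rng.permutation(m))
        if p not in seen:
            seen.add(p)
            perms.append(p)
    return perms


def run_nbic(matrix: LoadingMatrix, config: SearchConfig) -> list[Bicluster]:
    """Full search: sort -> permute -> Search_BiC -> stability filter.

    Returns the stable biclusters (frequency >= ``config.min_frequency``)
    with membership expressed in the matrix's subject identifiers and
    feature labels. Deterministic given ``config.seed``.
    """
    if matrix.n_features < config.K:
        raise ValueError(
            f"fewer features ({matrix.n_features}) than the minimum K={config.K}"
        )
    scomp_list = sort_all(matrix, config.M)
    scomps = _scomp_map(scomp_list)
    thresholds = compute_thresholds(config.N, config.K, config.O, config.OE)
    ids = tuple(sorted(scomps))
    perms = sample_permutations(ids, config.permutation_budget, config.seed)
    logger.info(
        "searching %d features over %d permutations (N=%d, K=%d, fTH1=%.2f, fTH2=%.2f)",
        len(ids), len(perms), config.N, config.K, thresholds.fth1, thresholds.fth2,
    )

    cache: dict = {}
    final: list[Bicluster] = []
    for p, perm in enumerate(perms):
        temp = search_bic(perm, scomps, config, thresholds, _cache=cache)
        # first permutation: nothing earlier to check against; global_update
        # on an empty list appends everything with frequency 1
        final = global_update(final, temp, thresholds.fth2)
        if (p + 1) % 100 == 0:
            logger.debug("permutation %d/%d: %d biclusters", p + 1, len(perms), len(final))

    stable = stability_filter(final, config.min_frequency)
    logger.info("%d biclusters found, %d stable", len(final), len(stable))
    id_to_label = {i + 1: sc.feature_label for i, sc in enumerate(scomp_list)}
    return [
        Bicluster(b.subject_set, frozenset(id_to_label[f] for f in b.feature_set), b.frequency)
        for b in stable
    ]
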