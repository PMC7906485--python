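"""Bicluster-symptom association: correlation, FDR correction, selection.

For each bicluster, a subject's composite expression is the mean loading
over the bicluster's *imaging* features; that composite is correlated
(Pearson) with each symptom score across the bicluster's subjects. P-values
are Benjamini-Hochberg adjusted per symptom (each symptom's column forms
its own family, matching a per-symptom report table), or globally across
all pairs if requested. A bicluster is significant if, for at least one
symptom, |r| >= r_min and adjusted p <= alpha. A bicluster whose feature
set contains every symptom column is labelled a SYMBiC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import Bicluster, LoadingMatrix, SymptomTable

__all__ = [
    "AssociationResult",
    "bic_symptom_correlation",
    "fdr_adjust",
    "associate_biclusters",
    "select_significant",
    "symptom_summary",
]


@dataclass
class AssociationResult:
    """Correlation of one bicluster with one symptom score."""

    bicluster_id: int
    symptom: object
    r: float
    p: float
    p_adj: float = np.nan
    significant: bool = False
    symbic: bool = False
    computable: bool = True


def _composite_loading(
    matrix: LoadingMatrix, bic: Bicluster, subject_ids
) -> np.ndarray:
    """Mean loading over the bicluster's imaging features, per subject."""
    imaging = [f for f in bic.feature_set if f in set(matrix.imaging_labels)]
    if not imaging:
        raise ValueError("bicluster has no imaging features to average")
    cols = [matrix.feature_labels.index(f) for f in sorted(imaging, key=str)]
    rows = [matrix.subject_ids.index(s) for s in subject_ids]
    return matrix.values[np.ix_(rows, cols)].mean(axis=1)


def bic_symptom_correlation(
    matrix: LoadingMatrix,
    symptoms: SymptomTable,
    bic: Bicluster,
    subjects: str = "bicluster",
) -> dict:
    """Pearson (r, p) of a bicluster's composite loading with every symptom.

    ``subjects="bicluster"`` (default) correlates across the bicluster's own
    subjects; ``subjects="all"`` uses every subject shared by the matrix and
    the symptom table. Pairs with fewer than 3 usable subjects or a constant
    variable are flagged not-computable (r and p are NaN) rather than left
    as silent NaN.
    """
    if subjects == "bicluster":
        shared = [s for s in matrix.subject_ids if s in bic.subject_set]
    elif subjects == "all":
        shared = list(matrix.subject_ids)
    else:
        raise ValueError("subjects must be 'bicluster' or 'all'")
    sym_index = {s: i for i, s in enumerate(symptoms.subject_ids)}
    shared = [s for s in shared if s in sym_index]
    missing = bic.subject_set - set(sym_index) if subjects == "bicluster" else set()
    if missing:
        raise ValueError(
            f"{len(missing)} bicluster subjects have no symptom scores"
        )

    out = {}
    if len(shared) < 3:
        for label in symptoms.score_labels:
            out[label] = (np.nan, np.nan, False)
        return out
    composite = _composite_loading(matrix, bic, shared)
    rows = [sym_index[s] for s in shared]
    for k, label in enumerate(symptoms.score_labels):
        score = symptoms.values[rows, k]
        if np.std(score) == 0 or np.std(composite) == 0:
            out[label] = (np.nan, np.nan, False)
            continue
        r, p = stats.pearsonr(composite, score)
        out[label] = (float(r), float(p), True)
    return out


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def associate_biclusters(
    matrix: LoadingMatrix,
    symptoms: SymptomTable,
    bics: list[Bicluster],
    r_min: float = 0.4,
    alpha: float = 0.05,
    fdr_family: str = "per-symptom",
    subjects: str = "bicluster",
) -> list[AssociationResult]:
    """Correlate every bicluster with every symptom and adjust for FDR.

    Returns one :class:`AssociationResult` per (bicluster, symptom) pair;
    bicluster IDs are 1-based positions in ``bics``. Significance requires
    |r| >= r_min and adjusted p <= alpha.
    """
    if fdr_family not in ("per-symptom", "global"):
        raise ValueError("fdr_family must be 'per-symptom' or 'global'")
    symptom_set = set(symptoms.score_labels)
    results: list[AssociationResult] = []
    for b_id, bic in enumerate(bics, start=1):
        per_symptom = bic_symptom_correlation(matrix, symptoms, bic, subjects)
        symbic = symptom_set <= bic.feature_set
        for label in symptoms.score_labels:
            r, p, ok = per_symptom[label]
            results.append(
                AssociationResult(b_id, label, r, p, symbic=symbic, computable=ok)
            )

    # FDR family: each symptom's column of p-values, or all pairs at once
    if fdr_family == "per-symptom":
        families = [
            [res for res in results if res.symptom == label]
            for label in symptoms.score_labels
        ]
    else:
        families = [results]
    for family in families:
        usable = [res for res in family if res.computable]
        if usable:
            adjusted = fdr_adjust([res.p for res in usable])
            for res, p_adj in zip(usable, adjusted):
                res.p_adj = float(p_adj)

    select_significant(results, r_min, alpha)
    return results


def select_significant(
    results: list[AssociationResult], r_min: float = 0.4, alpha: float = 0.05
) -> list[int]:
    """Flag biclusters with |r| >= r_min and adjusted p <= alpha somewhere.

    Sets ``significant`` in place on every result row of a flagged
    bicluster and returns the sorted flagged bicluster IDs.
    """
    flagged = set()
    for res in results:
        if res.computable and abs(res.r) >= r_min and res.p_adj <= alpha:
            flagged.add(res.bicluster_id)
    for res in results:
        res.significant = res.bicluster_id in flagged
    return sorted(flagged)


def symptom_summary(symptoms: SymptomTable, bic: Bicluster) -> pd.DataFrame:
    """Mean and sample SD of every symptom score over a bicluster's subjects."""
    rows = [i for i, s in enumerate(symptoms.subject_ids) if s in bic.subject_set]
    if not rows:
        raise ValueError("no bicluster subjects present in the symptom table")
    sub = symptoms.values[rows, :]
    return pd.DataFrame(
        {
            "symptom": list(symptoms.score_labels),
            "mean": sub.mean(axis=0),
            "sd": sub.std(axis=0, ddof=1) if sub.shape[0] > 1 else np.zeros(sub.shape[1]),
            "n": sub.shape[0],
        }
    )
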