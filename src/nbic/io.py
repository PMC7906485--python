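"""Readers and writers for loading matrices, symptom tables and reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .association import AssociationResult
from .types import Bicluster, LoadingMatrix, SymptomTable

__all__ = [
    "read_loading_matrix",
    "write_loading_matrix",
    "read_symptom_table",
    "write_bicluster_report",
    "read_bicluster_report",
]

_SEP = {"csv": ",", "tsv": "\t"}


def _dialect(path: Path, dialect: str | None) -> str:
    if dialect in _SEP:
        return dialect
    if dialect is not None:
        raise ValueError(f"unknown dialect {dialect!r}")
    return "tsv" if path.suffix.lower() in (".tsv", ".tab", ".txt") else "csv"


def _read_table(path, dialect):
    path = Path(path)
    frame = pd.read_csv(path, sep=_SEP[_dialect(path, dialect)], index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
            row = str(bad.index[0]) if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, row {row!r}"
            )
    if frame.isna().any().any():
        raise ValueError(f"{path}: missing values are not supported")
    return frame


def read_loading_matrix(
    path, dialect: str | None = None, symptom_columns: Iterable[str] = ()
) -> LoadingMatrix:
    """Read a subjects x features matrix from CSV/TSV.

    First row holds feature labels, first column subject IDs; all remaining
    cells must be numeric and non-missing. ``symptom_columns`` flags the
    named columns as symptom-kind features. The dialect is inferred from
    the extension when not given.
    """
    return LoadingMatrix.from_frame(_read_table(path, dialect), symptom_columns)


def write_loading_matrix(matrix: LoadingMatrix, path, dialect: str | None = None) -> None:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_SEP[_dialect(path, dialect)], index_label="subject")


def read_symptom_table(path, dialect: str | None = None) -> SymptomTable:
    """Read a subjects x scores table (same layout as the loading matrix)."""
    frame = _read_table(path, dialect)
    return SymptomTable(
        values=frame.to_numpy(dtype=float),
        subject_ids=tuple(frame.index),
        score_labels=tuple(frame.columns),
    )


def write_bicluster_report(
    bics: list[Bicluster],
    path_prefix,
    associations: list[AssociationResult] | None = None,
) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (one row per bicluster) and ``<prefix>.json``.

    The TSV holds bicluster ID, feature labels, subject count and stability
    frequency, plus per-symptom r / p / adjusted p and flags when
    association results are given. The JSON carries the full subject and
    feature membership, exactly re-readable with
    :func:`read_bicluster_report`.
    """
    prefix = Path(path_prefix)
    tsv_path, json_path = prefix.with_suffix(".tsv"), prefix.with_suffix(".json")

    by_bic: dict[int, list[AssociationResult]] = {}
    symptom_order: list = []
    for res in associations or []:
        by_bic.setdefault(res.bicluster_id, []).append(res)
        if res.symptom not in symptom_order:
            symptom_order.append(res.symptom)

    rows = []
    for b_id, b in enumerate(bics, start=1):
        row = {
            "bicluster": b_id,
            "features": ",".join(sorted(map(str, b.feature_set))),
            "n_subjects": b.n_subjects,
            "frequency": b.frequency,
        }
        if associations is not None:
            for label in symptom_order:
                match = [r for r in by_bic.get(b_id, []) if r.symptom == label]
                if match:
                    (res,) = match
                    row[f"r_{label}"] = res.r
                    row[f"p_{label}"] = res.p
                    row[f"p_adj_{label}"] = res.p_adj
                else:
                    row[f"r_{label}"] = row[f"p_{label}"] = row[f"p_adj_{label}"] = np.nan
            row["significant"] = any(r.significant for r in by_bic.get(b_id, []))
            row["symbic"] = any(r.symbic for r in by_bic.get(b_id, []))
        rows.append(row)

    columns = ["bicluster", "features", "n_subjects", "frequency"]
    if associations is not None:
        for label in symptom_order:
            columns += [f"r_{label}", f"p_{label}", f"p_adj_{label}"]
        columns += ["significant", "symbic"]
    pd.DataFrame(rows, columns=columns).to_csv(
        tsv_path, sep="\t", index=False, float_format="%.12g"
    )

    payload = [
        {
            "bicluster": b_id,
            "subjects": sorted(map(str, b.subject_set)),
            "features": sorted(map(str, b.feature_set)),
            "frequency": b.frequency,
        }
        for b_id, b in enumerate(bics, start=1)
    ]
    json_path.write_text(json.dumps(payload, indent=1))
    return tsv_path, json_path


def read_bicluster_report(json_path) -> list[Bicluster]:
    """Re-read the JSON membership report written by :func:`write_bicluster_report`."""
    payload = json.loads(Path(json_path).read_text())
    return [
        Bicluster(frozenset(e["subjects"]), frozenset(e["features"]), e["frequency"])
        for e in payload
    ]
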