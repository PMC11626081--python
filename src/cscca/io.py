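"""Readers and writers for abundance tables, groups, and results.

Tables are TSV/CSV with samples in rows and features in columns (an
orientation flag handles the transposed dialect common for OTU tables);
BIOM v1 (JSON) tables are also accepted.  Group/taxonomy files are
two-column TSV mapping feature_id -> group label.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import OmicsMatrix
from .solvers import CanonicalPair

__all__ = [
    "read_table",
    "write_table",
    "read_biom_v1",
    "read_groups",
    "write_coefficients",
    "read_coefficients",
    "write_metadata",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(
    path,
    compositional: bool = False,
    orientation: str = "samples_rows",
) -> OmicsMatrix:
    """Read a TSV/CSV abundance table into an OmicsMatrix.

    ``orientation="features_rows"`` transposes on read (the OTU-table
    dialect with taxa in rows).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "features_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError("orientation must be 'samples_rows' or 'features_rows'")
    return OmicsMatrix.from_dataframe(df, compositional=compositional)


def write_table(M: OmicsMatrix, path) -> None:
    path = Path(path)
    M.to_dataframe().to_csv(path, sep=_sep_for(path))


def read_biom_v1(path, compositional: bool = True) -> OmicsMatrix:
    """Read a BIOM format v1 (JSON) table.

    BIOM v1 stores features ("rows") x samples ("columns") either dense
    or sparse; the result is transposed to samples x features.
    """
    with open(path) as fh:
        doc = json.load(fh)
    feature_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    return OmicsMatrix(
        values=mat.T,
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        compositional=compositional,
    )


def read_groups(path) -> dict:
    """Read a two-column TSV (feature_id, group_label) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["feature_id", "group"], dtype=str)
    return dict(zip(df["feature_id"], df["group"]))


def write_coefficients(
    path,
    pair: CanonicalPair,
    ids_a: list,
    ids_b: list,
    weights: dict | None = None,
) -> None:
    """Serialize a fitted pair as a long table (feature, side, coef, weight)."""
    wa = weights.get("a") if weights else None
    wb = weights.get("b") if weights else None
    rows = []
    for j, fid in enumerate(ids_a):
        rows.append(
            {
                "feature_id": fid,
                "side": "a",
                "coefficient": pair.a[j],
                "weight": float(wa[j]) if wa is not None else 1.0,
            }
        )
    for j, fid in enumerate(ids_b):
        rows.append(
            {
                "feature_id": fid,
                "side": "b",
                "coefficient": pair.b[j],
                "weight": float(wb[j]) if wb is not None else 1.0,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_coefficients(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_metadata(path, **fields) -> None:
    """Write a JSON run-metadata record (penalties, seeds, diagnostics)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
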