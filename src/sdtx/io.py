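"""Readers/writers for expression matrices, sample metadata and GMT gene sets.

File dialects
-------------
Expression: TSV, first column the gene symbol, remaining columns sample ids,
UTF-8, ``.`` decimal.  Metadata: TSV with columns ``sample_id, subject_id,
timepoint, group, age, sex, protocol_violation``.  Gene sets: standard GMT
(name, description, members..., tab-separated).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionStudy, GeneSetCollection, META_COLUMNS, StudyValidationError


def read_expression(expr_path: str | Path, meta_path: str | Path) -> ExpressionStudy:
    """Read a genes × samples TSV plus its sample-metadata TSV.

    Raises
    ------
    StudyValidationError
        If sample ids differ between the two files (offenders are named) or
        metadata columns are missing.
    ValueError
        If an expression cell is non-numeric (coordinates are reported).
    """
    expr = pd.read_csv(
        expr_path, sep="\t", index_col=0, dtype=str, float_precision="round_trip"
    )
    numeric = expr.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & expr.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value {expr.iat[g, s]!r} at "
            f"gene {expr.index[g]!r}, sample {expr.columns[s]!r} in {expr_path}"
        )
    meta = read_metadata(meta_path)
    return ExpressionStudy(numeric.astype(float), meta)


def read_metadata(meta_path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(
        meta_path,
        sep="\t",
        dtype={"sample_id": str, "subject_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise StudyValidationError(f"{meta_path}: metadata missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        dup = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"])
        raise StudyValidationError(f"{meta_path}: duplicate sample ids {dup}")
    meta = meta.set_index("sample_id")
    meta["age"] = meta["age"].astype(float)
    meta["protocol_violation"] = _parse_bool(meta["protocol_violation"])
    return meta


def _parse_bool(col: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False,
    }
    return col.astype(str).str.strip().str.lower().map(mapping).astype(bool)


def write_expression(
    study: ExpressionStudy, expr_path: str | Path, meta_path: str | Path
) -> None:
    """Write the canonical TSV pair (inverse of :func:`read_expression`)."""
    study.values.to_csv(expr_path, sep="\t", index_label="gene", float_format="%.10g")
    meta = study.samples.copy()
    meta.insert(0, "sample_id", meta.index)
    meta.to_csv(meta_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT gene-set file (name, description, members per line)."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line "
                    f"(expected >= 3 tab-separated fields, got {len(fields)})"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = [g for g in fields[2:] if g.strip()]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection:
            fh.write("\t".join([name, collection.source or "na", *members]) + "\n")


def load_circadian_panel() -> list[str]:
    """The packaged circadian panel: 10 canonical clock genes plus 13 further
    blood-rhythmicity predictor genes (23 unique symbols; PER1 and NR1D2 sit
    on both source lists)."""
    text = (
        importlib.resources.files("sdtx")
        .joinpath("resources/circadian_panel.txt")
        .read_text(encoding="utf-8")
    )
    panel: list[str] = []
    for line in text.splitlines():
        line = line.strip().upper()
        if line and not line.startswith("#") and line not in panel:
            panel.append(line)
    return panel


def read_panel(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line panel file (``#`` comments allowed)."""
    panel: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip().upper()
        if line and not line.startswith("#") and line not in panel:
            panel.append(line)
    return panel
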