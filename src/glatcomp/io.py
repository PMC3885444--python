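"""Readers and writers for the plain-text formats the pipeline consumes.

Expression matrices are TSV with probes in rows; sample sheets CSV/TSV with
five named columns; gene sets GMT; orthology maps two-column TSV; cell-type
references gene × cell-type TSV.  Output tables carry a ``#`` comment line
recording tool version and parameters.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    CellTypeReference,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    OrthologyMap,
    ProbeAnnotation,
    SampleMetadata,
    parse_treatment,
)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "write_gmt",
    "read_orthology_map",
    "read_probe_annotation",
    "read_celltype_reference",
    "write_celltype_reference",
    "write_table",
    "maybe_log2",
]


def _comment(params: dict | None) -> str:
    items = "" if not params else " " + " ".join(f"{k}={v}" for k, v in params.items())
    return f"# glatcomp {__version__}{items}\n"


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited probe × sample matrix.

    First column = probe IDs, header row = sample IDs.  Duplicated IDs and
    non-numeric cells are hard errors with the offending location named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    dup_probes = df.index[df.index.duplicated()].unique().tolist()
    if dup_probes:
        raise ValueError(f"duplicate probe IDs in {path}: {dup_probes}")
    dup_samples = [c for c in df.columns if list(df.columns).count(c) > 1]
    if dup_samples:
        raise ValueError(f"duplicate sample IDs in {path}: {sorted(set(dup_samples))}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy()
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = df.index[bad.isna().to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric value at probe {row!r}, sample {col!r} in {path}"
            ) from None
    out = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))
    return ExpressionMatrix(out)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, params: dict | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_comment(params))
        matrix.data.to_csv(fh, sep="\t", index_label="probe_id", float_format="%.10g")


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_sample_sheet(path: str | Path) -> SampleMetadata:
    """Read a sample sheet (CSV or TSV) into :class:`SampleMetadata`.

    Required columns: sample_id, treatment, chip_batch, product_batch,
    replicate_group.  Unknown treatment strings map to OTHER with a warning.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, comment="#")
    missing = [c for c in (
        "sample_id", "treatment", "chip_batch", "product_batch", "replicate_group"
    ) if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing required column(s): {missing}")
    df = df.set_index("sample_id")
    df["treatment"] = [parse_treatment(t) for t in df["treatment"]]
    return SampleMetadata(df)


def write_sample_sheet(meta: SampleMetadata, path: str | Path) -> None:
    out = meta.table.copy()
    out["treatment"] = [t.value for t in out["treatment"]]
    out.to_csv(path, index_label="sample_id")


def read_gmt(path: str | Path, normalize_case: bool = True) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"malformed GMT line {lineno} in {path}: expected >=3 "
                    f"tab-separated fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise ValueError(f"gene set at line {lineno} in {path} has no members")
            sets.append(GeneSet(name, desc, tuple(genes)))
    return GeneSetCollection(sets, normalize_case=normalize_case)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            gs = collection[name]
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_orthology_map(path: str | Path) -> OrthologyMap:
    """Read a two-column TSV of source → target gene symbols."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"malformed orthology line {lineno} in {path}: need 2 columns"
                )
            pairs.append((fields[0], fields[1]))
    return OrthologyMap(pairs)


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read probe_id → gene symbol TSV (two columns, header optional)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"malformed annotation line {lineno} in {path}: need 2 columns"
                )
            if lineno == 1 and fields[0].lower() in {"probe_id", "probe"}:
                continue
            mapping[fields[0]] = fields[1]
    return ProbeAnnotation(mapping)


def read_celltype_reference(path: str | Path) -> CellTypeReference:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return CellTypeReference(df)


def write_celltype_reference(ref: CellTypeReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_comment(None))
        ref.data.to_csv(fh, sep="\t", index_label="gene", float_format="%.10g")


def write_table(df: pd.DataFrame, path: str | Path, params: dict | None = None,
                index_label: str | None = None) -> None:
    """Write an output TSV with the standard version/parameter comment line."""
    with open(path, "w") as fh:
        fh.write(_comment(params))
        df.to_csv(fh, sep="\t", index=index_label is not None,
                  index_label=index_label, float_format="%.10g")


def maybe_log2(matrix: ExpressionMatrix, mode: str = "auto") -> ExpressionMatrix:
    """Log2-transform linear-scale intensities.

    mode='auto' transforms iff the matrix maximum exceeds 50 (log2 microarray
    data rarely exceeds ~16); 'yes' forces the transform, 'no' passes through.
    A +1 offset guards background-corrected intensities near zero.
    """
    if mode not in {"auto", "yes", "no"}:
        raise ValueError(f"invalid log2 mode {mode!r}")
    do = mode == "yes" or (mode == "auto" and float(matrix.values.max()) > 50)
    if not do:
        return matrix
    vals = matrix.values
    if vals.min() < -1:
        raise ValueError("cannot log2-transform: intensities below -1 present")
    warnings.warn("log2-transforming input intensities", stacklevel=2)
    return ExpressionMatrix(
        pd.DataFrame(np.log2(vals + 1.0), index=matrix.data.index,
                     columns=matrix.data.columns)
    )
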