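"""TSV readers and writers for matrices, designs, annotations and tables.

All interchange is plain tab-separated text. Floats are written with 17
significant digits so write -> read round-trips are exact to double
precision.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .matrix import ExpressionMatrix, TranscriptAnnotation

FLOAT_FMT = "%.17g"


def read_expression_tsv(path, unit: str = "TPM", design: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Expression matrix from TSV: header = sample ids, first column = feature ids.

    Ragged rows, non-numeric cells and duplicate feature ids raise with the
    offending line number / id.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        line = list(df.index).index(dup) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: duplicate feature id {dup!r} (line {line})")
    try:
        values = df.astype(float)
    except ValueError as exc:
        for lineno, (_, row) in enumerate(df.iterrows(), start=2):
            for v in row:
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell {v!r} at line {lineno}"
                    ) from exc
        raise
    if values.isna().any().any():
        gene = values.index[values.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing value in row {gene!r} (ragged row?)")
    return ExpressionMatrix(values, unit, design)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="feature_id")


def read_design_tsv(path) -> pd.DataFrame:
    """Sample design: columns sample, muscle, condition (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "muscle", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: design needs columns {sorted(required)}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return df.set_index("sample")


def write_design_tsv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index_label="sample")


def read_annotation_tsv(path) -> TranscriptAnnotation:
    """Transcript annotation: columns transcript_id, gene_id, length."""
    df = pd.read_csv(path, sep="\t")
    return TranscriptAnnotation(df)


def write_annotation_tsv(annotation: TranscriptAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def read_pseudoalignments_tsv(path) -> list[tuple[str, list[str]]]:
    """Pseudoalignments: read_id TAB comma-separated candidate transcript ids."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'read_id<TAB>tx1,tx2,...'")
            read_id, txs = parts
            records.append((read_id, [t for t in txs.split(",") if t]))
    return records


def write_pseudoalignments_tsv(records, path) -> None:
    with open(path, "w") as fh:
        for read_id, txs in records:
            fh.write(f"{read_id}\t{','.join(txs)}\n")


def write_table_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)
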