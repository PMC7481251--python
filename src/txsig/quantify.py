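"""Read counting, TPM/CPM, gene aggregation, filtering and fold changes.

Multi-mapping reads are assigned fractionally: a read compatible with n
transcripts contributes 1/n to each, so total counts always equal the number
of reads. TPM for transcript i with count c_i and length l_i is

    t_i = (c_i / l_i) / sum_j (c_j / l_j) * 1e6.

Gene-level values are sums over a gene's transcripts (valid for counts and
for TPM alike). Genes are kept when they reach a unit threshold (1 CPM or
1 TPM by convention) in at least as many samples as the smallest design
group. Fold changes are simplified normalized-mean log2 ratios; the ranked
logFC vector is what every downstream stage consumes, so any external
estimator producing the same shape can be swapped in.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, TranscriptAnnotation


def weighted_counts(
    alignments: Iterable[tuple[str, Sequence[str]]],
    annotation: TranscriptAnnotation | None = None,
) -> pd.Series:
    """Fractional transcript counts from read -> candidate-transcript records.

    A uniquely mapped read adds 1 to its transcript; a read listing n
    candidates adds 1/n to each. Records with an empty candidate list are
    rejected with a warning (their count is reported in the Series' attrs).

    Returns
    -------
    pd.Series
        Count per transcript, name ``count``. ``attrs['n_reads']`` holds the
        number of valid reads and ``attrs['n_rejected']`` the rejected ones.
    """
    counts: dict[str, float] = {}
    n_reads = 0
    n_rejected = 0
    known = set(annotation.transcript_ids) if annotation is not None else None
    for read_id, txs in alignments:
        txs = list(txs)
        if not txs:
            n_rejected += 1
            continue
        if known is not None:
            unknown = [t for t in txs if t not in known]
            if unknown:
                raise KeyError(f"read {read_id!r} lists unannotated transcripts {unknown[:3]}")
        n_reads += 1
        w = 1.0 / len(txs)
        for t in txs:
            counts[t] = counts.get(t, 0.0) + w
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} reads with empty transcript lists")
    if annotation is not None:
        out = pd.Series(0.0, index=annotation.transcript_ids, name="count")
        for t, c in counts.items():
            out[t] = c
    else:
        out = pd.Series(counts, name="count").sort_index()
    out.attrs["n_reads"] = n_reads
    out.attrs["n_rejected"] = n_rejected
    return out


def tpm(counts: pd.Series, annotation: TranscriptAnnotation) -> pd.Series:
    """Transcripts-per-million from counts and transcript lengths.

    An all-zero sample yields an all-zero column flagged in attrs rather
    than NaNs.
    """
    if (counts < 0).any():
        raise ValueError("negative counts")
    lengths = annotation.lengths(counts.index)
    rate = counts.to_numpy(dtype=float) / lengths
    total = rate.sum()
    out = pd.Series(np.zeros_like(rate), index=counts.index, name="TPM")
    if total == 0:
        out.attrs["degenerate"] = True
        warnings.warn("all-zero sample: TPM undefined, returning zeros")
        return out
    out[:] = rate / total * 1e6
    out.attrs["degenerate"] = False
    return out


def cpm(counts: pd.Series) -> pd.Series:
    """Counts-per-million (library-size normalization without lengths)."""
    if (counts < 0).any():
        raise ValueError("negative counts")
    total = counts.sum()
    out = pd.Series(np.zeros(len(counts)), index=counts.index, name="CPM")
    if total == 0:
        out.attrs["degenerate"] = True
        warnings.warn("all-zero sample: CPM undefined, returning zeros")
        return out
    out[:] = counts.to_numpy(dtype=float) / total * 1e6
    out.attrs["degenerate"] = False
    return out


def tpm_matrix(count_matrix: ExpressionMatrix, annotation: TranscriptAnnotation) -> ExpressionMatrix:
    """Column-wise TPM of a transcript-level count matrix."""
    cols = {s: tpm(count_matrix.values[s], annotation) for s in count_matrix.sample_ids}
    values = pd.DataFrame(cols)[count_matrix.sample_ids]
    values.index = count_matrix.feature_ids
    return count_matrix.with_values(values, unit="TPM")


def aggregate_to_genes(
    matrix: ExpressionMatrix, annotation: TranscriptAnnotation
) -> ExpressionMatrix:
    """Sum transcript-level values into gene-level values.

    Column sums are preserved exactly because genes partition transcripts.
    """
    genes = annotation.gene_of(matrix.feature_ids)
    values = matrix.values.groupby(genes.to_numpy()).sum()
    values.index.name = "gene_id"
    return matrix.with_values(values)


def min_group_size(design: pd.DataFrame) -> int:
    """Smallest number of samples in any (muscle, condition) group."""
    if design is None or len(design) == 0:
        raise ValueError("empty design table")
    sizes = design.groupby(["muscle", "condition"]).size()
    return int(sizes.min())


def expression_filter(
    matrix: ExpressionMatrix, threshold: float = 1.0, unit: str | None = None
) -> ExpressionMatrix:
    """Keep genes reaching `threshold` in at least min-group-size samples.

    The sample count is taken matrix-wide (not per group): a gene expressed
    at >= 1 unit in as many samples as the smallest group could in principle
    be consistently expressed in one whole group. Filtering is idempotent.
    """
    if unit is not None and matrix.unit != unit:
        raise ValueError(f"matrix unit is {matrix.unit}, filter expects {unit}")
    k = min_group_size(matrix.design)
    keep = (matrix.values >= threshold).sum(axis=1) >= k
    return matrix.with_values(matrix.values.loc[keep])


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1); the unit tag becomes logTPM."""
    if matrix.unit != "TPM":
        raise ValueError(f"log transform expects TPM input, got {matrix.unit}")
    if (matrix.values < 0).any().any():
        raise ValueError("negative expression values")
    return matrix.with_values(np.log2(matrix.values + 1.0), unit="logTPM")


def log_fold_changes(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean_A + pc) / (mean_B + pc)) on normalized values.

    `contrast` names two groups from the design: either full
    '<muscle>:<condition>' labels or bare condition labels (pooling
    muscles). Swapping A and B negates every value.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if matrix.unit == "logTPM":
        raise ValueError("fold changes are computed on linear-scale values (counts/CPM/TPM)")
    group_a, group_b = contrast
    a = matrix.values[matrix.samples_in_group(group_a)].mean(axis=1)
    b = matrix.values[matrix.samples_in_group(group_b)].mean(axis=1)
    lfc = np.log2((a + pseudocount) / (b + pseudocount))
    lfc.name = f"logFC({group_a}/{group_b})"
    return lfc
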