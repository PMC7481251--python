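"""From multi-mapped reads to gene-level TPM.

Builds a 3-transcript annotation, simulates pseudoalignment records with
multi-mapping, applies the 1/n weighted assignment rule, converts to TPM
and aggregates transcripts into genes.
"""

import pandas as pd

from txsig import (
    ExpressionMatrix,
    TranscriptAnnotation,
    aggregate_to_genes,
    generate_pseudoalignments,
    tpm,
    weighted_counts,
)

annotation = TranscriptAnnotation(
    pd.DataFrame(
        {
            "transcript_id": ["t1", "t2", "t3"],
            "gene_id": ["gA", "gA", "gB"],
            "length": [1000, 2000, 500],
        }
    )
)

truth = pd.Series([120, 60, 30], index=["t1", "t2", "t3"])
records = generate_pseudoalignments(annotation, truth, multimap_rate=0.3, seed=1)
print(f"{len(records)} reads emitted (equals the true total {truth.sum()})")

counts = weighted_counts(records, annotation)
print("weighted counts:", {k: float(v) for k, v in counts.round(2).items()})
# Multi-mapped reads are split 1/n across their candidates, so the total
# count still equals the number of reads even though per-transcript counts
# become fractional.

expr = tpm(counts, annotation)
print("TPM:", {k: float(v) for k, v in expr.round(1).items()}, "| column sum:", round(expr.sum(), 6))
# TPM divides counts by transcript length before normalizing to 1e6, so the
# short t3 gains relative to its raw count share.

gene_level = aggregate_to_genes(
    ExpressionMatrix(expr.to_frame("s1"), "TPM"), annotation
)
print("gene-level TPM:", {k: float(v) for k, v in gene_level.values['s1'].round(1).items()})
# gA sums its two isoforms; column totals are preserved.
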