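"""Planted-signature recovery in the simulated multi-muscle experiment.

Simulates 4 muscles x 3 conditions (young control, aged control, aged+drug)
x 6 animals with 100 genes displaced along a shared aging axis, runs the
filter -> log -> double-center -> SVD -> alignment pipeline, locates the PC
separating young from aged samples, and scores recovery of the planted
genes.
"""

from txsig import (
    DesignSpec,
    aligned_genes,
    default_signature,
    double_center,
    expression_filter,
    find_condition_pc,
    generate_multimuscle,
    log_transform,
    svd_decompose,
)

design = DesignSpec(n_genes=2000)
signature = default_signature(design, n_up=50, n_down=50, effect_size=1.0)
matrix, truth = generate_multimuscle(design, signature, noise_sd=0.3, seed=1)

logm = log_transform(expression_filter(matrix))
decomp = svd_decompose(double_center(logm))
print("variance fractions:", [round(float(x), 3) for x in decomp.lam[:6]])
# The top PCs carry muscle identity (they are condition-independent); the
# planted aging axis appears further down the spectrum, as in real
# multi-tissue designs.

aging_pc = find_condition_pc(decomp, matrix.design, "10mCON", "30mCON")
print("aging PC:", aging_pc)

sets = aligned_genes(decomp, aging_pc)
called = sets.all_signed
nulls = frozenset(map(str, decomp.gene_ids)) - truth.planted
sensitivity = len(called & truth.planted) / len(truth.planted)
fpr = len(called & nulls) / len(nulls)
print(f"sensitivity {sensitivity:.3f}, false-positive rate {fpr:.5f}")
# At effect 1.0 log2 and noise 0.3 the alignment rule recovers essentially
# all planted genes while calling almost no null genes.
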