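"""Synthetic expression data with recorded ground truth.

Three generators emulate the structures the analysis assumes, so that every
downstream stage can be exercised and calibrated without any external data:

* a multi-muscle / multi-condition experiment (default: 4 muscles x 3
  conditions x 6 animals, mirroring a young-control / aged-control /
  aged-plus-drug design) with per-gene muscle-identity offsets, a planted
  aging signature whose strength can scale per muscle, and a per-muscle
  reversal coefficient describing how the drug condition modifies the
  planted aging effect (-1 erases it, 0 leaves it, +1 doubles it);
* the 26-gene x 3-sample toy: 20 null genes sharing a location across
  samples and 3+3 genes shifted up/down in sample 3 only;
* pseudoalignment records (read -> candidate transcript lists) to exercise
  the weighted 1/n read-assignment rule.

Everything is driven by an explicit seed and returns its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, TranscriptAnnotation

MUSCLES = ("TA", "TRI", "GAS", "SOL")
CONDITIONS = ("10mCON", "30mCON", "30mRM")


@dataclass
class DesignSpec:
    """Experimental layout of the simulated study.

    groups: (muscle, condition, n_samples) triples; baseline_log_mean/sd
    describe the log2-scale spread of gene baselines; muscle_offset_sd is
    the per-gene, per-muscle identity effect; library_size is the expected
    read count per sample when counts are requested.
    """

    groups: list[tuple[str, str, int]] = field(
        default_factory=lambda: [(m, c, 6) for m in MUSCLES for c in CONDITIONS]
    )
    n_genes: int = 2000
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 2.0
    muscle_offset_sd: float = 0.5
    library_size: float = 2e7

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("need at least 10 genes")
        seen = set()
        for muscle, condition, n in self.groups:
            if n < 2:
                raise ValueError(f"group ({muscle}, {condition}) has n_samples={n} < 2")
            if (muscle, condition) in seen:
                raise ValueError(f"duplicate group ({muscle}, {condition})")
            seen.add((muscle, condition))

    @property
    def muscles(self) -> list[str]:
        return list(dict.fromkeys(m for m, _, _ in self.groups))

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(c for _, c, _ in self.groups))

    def gene_ids(self) -> pd.Index:
        width = len(str(self.n_genes))
        return pd.Index([f"g{i + 1:0{width}d}" for i in range(self.n_genes)], name="gene_id")

    def design_table(self) -> pd.DataFrame:
        rows = []
        for muscle, condition, n in self.groups:
            for i in range(1, n + 1):
                rows.append((f"{muscle}_{condition}_{i}", muscle, condition))
        return pd.DataFrame(rows, columns=["sample", "muscle", "condition"]).set_index("sample")


@dataclass
class PlantedSignature:
    """Genes displaced along the simulated aging axis.

    direction: +1/-1 per planted gene id; effect_size: log2 displacement in
    the aged condition; muscle_scaling: per-muscle multiplier of that
    effect; reversal_coefficient: per-muscle r in [-1, 1] so the drug
    condition carries (1 + r) times the aging term.
    """

    direction: dict[str, int]
    effect_size: float = 1.0
    muscle_scaling: dict[str, float] = field(default_factory=dict)
    reversal_coefficient: dict[str, float] = field(default_factory=dict)
    aged_condition: str = "30mCON"
    drug_condition: str = "30mRM"
    young_condition: str = "10mCON"

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        bad = [g for g, d in self.direction.items() if d not in (-1, 1)]
        if bad:
            raise ValueError(f"directions must be +1/-1; offenders: {bad[:5]}")
        for m, r in self.reversal_coefficient.items():
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"reversal_coefficient[{m}]={r} outside [-1, 1]")

    @property
    def up_genes(self) -> frozenset:
        return frozenset(g for g, d in self.direction.items() if d == 1)

    @property
    def down_genes(self) -> frozenset:
        return frozenset(g for g, d in self.direction.items() if d == -1)


def default_signature(
    design: DesignSpec,
    n_up: int = 50,
    n_down: int = 50,
    effect_size: float = 1.0,
    muscle_scaling: dict[str, float] | None = None,
    reversal_coefficient: dict[str, float] | None = None,
) -> PlantedSignature:
    """Plant the first n_up gene ids up and the next n_down down."""
    genes = design.gene_ids()
    if n_up + n_down > len(genes):
        raise ValueError("more planted genes than genes in the design")
    direction = {g: 1 for g in genes[:n_up]}
    direction.update({g: -1 for g in genes[n_up : n_up + n_down]})
    return PlantedSignature(
        direction,
        effect_size=effect_size,
        muscle_scaling=muscle_scaling or {},
        reversal_coefficient=reversal_coefficient or {},
    )


@dataclass
class GroundTruth:
    """What was planted, for self-contained downstream checks."""

    up_genes: frozenset
    down_genes: frozenset
    effect_size: float
    muscle_scaling: dict[str, float]
    reversal_coefficient: dict[str, float]
    noise_sd: float
    seed: int

    @property
    def planted(self) -> frozenset:
        return self.up_genes | self.down_genes


def generate_multimuscle(
    design: DesignSpec | None = None,
    signature: PlantedSignature | None = None,
    noise_sd: float = 0.3,
    seed: int = 1,
    output: str = "TPM",
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the multi-muscle aging/drug experiment.

    log2 expression = gene baseline + muscle-identity offset (one draw per
    gene x muscle) + direction * effect_size * muscle_scaling for planted
    genes in the aged condition, with the drug condition carrying
    (1 + reversal_coefficient) times that term, + iid Gaussian noise. The
    matrix is exponentiated and each sample rescaled to 1e6 (TPM); with
    output="counts", Poisson counts at the design library size are drawn
    instead.
    """
    design = design or DesignSpec()
    signature = signature or default_signature(design)
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if output not in ("TPM", "counts"):
        raise ValueError("output must be 'TPM' or 'counts'")
    genes = design.gene_ids()
    unknown = set(signature.direction) - set(genes)
    if unknown:
        raise ValueError(f"planted genes absent from the design: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(seed)
    n = design.n_genes
    muscles = design.muscles
    baseline = rng.normal(design.baseline_log_mean, design.baseline_log_sd, size=n)
    muscle_offset = {m: rng.normal(0.0, design.muscle_offset_sd, size=n) for m in muscles}

    dir_vec = np.zeros(n)
    for i, g in enumerate(genes):
        if g in signature.direction:
            dir_vec[i] = signature.direction[g]

    design_table = design.design_table()
    cols = {}
    for sample, row in design_table.iterrows():
        m, c = row["muscle"], row["condition"]
        x = baseline + muscle_offset[m]
        scale = signature.muscle_scaling.get(m, 1.0)
        aging_term = dir_vec * signature.effect_size * scale
        if c == signature.aged_condition:
            x = x + aging_term
        elif c == signature.drug_condition:
            x = x + (1.0 + signature.reversal_coefficient.get(m, 0.0)) * aging_term
        cols[sample] = x + rng.normal(0.0, noise_sd, size=n)
    log2x = pd.DataFrame(cols, index=genes)

    linear = np.exp2(log2x)
    tpm_values = linear / linear.sum(axis=0) * 1e6
    if output == "TPM":
        matrix = ExpressionMatrix(tpm_values, "TPM", design_table)
    else:
        lam = tpm_values / 1e6 * design.library_size
        counts = pd.DataFrame(
            rng.poisson(lam.to_numpy()), index=genes, columns=tpm_values.columns, dtype=float
        )
        matrix = ExpressionMatrix(counts, "counts", design_table)
    truth = GroundTruth(
        up_genes=signature.up_genes,
        down_genes=signature.down_genes,
        effect_size=signature.effect_size,
        muscle_scaling={m: signature.muscle_scaling.get(m, 1.0) for m in muscles},
        reversal_coefficient={m: signature.reversal_coefficient.get(m, 0.0) for m in muscles},
        noise_sd=noise_sd,
        seed=seed,
    )
    return matrix, truth


@dataclass
class ToySpec:
    """The 26-gene x 3-sample illustrative data set.

    Null genes share one location across samples; n_up/n_down genes are
    shifted by +-effect_size in the last sample only. Defaults keep the
    planted genes cleanly separable by the alignment rule.
    """

    n_null: int = 20
    n_up: int = 3
    n_down: int = 3
    n_samples: int = 3
    effect_size: float = 2.0
    noise_sd: float = 0.25
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 2.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if min(self.n_null, self.n_up, self.n_down) < 0:
            raise ValueError("negative gene counts")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.n_null + self.n_up + self.n_down


def generate_toy(spec: ToySpec | None = None) -> tuple[ExpressionMatrix, pd.Series]:
    """Toy matrix plus per-gene truth labels (null / up / down)."""
    spec = spec or ToySpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    baseline = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=n)
    X = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(n, spec.n_samples))
    lo, hi = spec.n_null, spec.n_null + spec.n_up
    X[lo:hi, -1] += spec.effect_size
    X[hi:, -1] -= spec.effect_size
    genes = pd.Index([f"g{i + 1:02d}" for i in range(n)], name="gene_id")
    samples = [f"s{j + 1}" for j in range(spec.n_samples)]
    labels = pd.Series(
        ["null"] * spec.n_null + ["up"] * spec.n_up + ["down"] * spec.n_down,
        index=genes,
        name="truth",
    )
    values = pd.DataFrame(X, index=genes, columns=samples)
    design = pd.DataFrame(
        {"muscle": "toy", "condition": [f"s{j + 1}" for j in range(spec.n_samples)]},
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionMatrix(values, "logTPM", design), labels


def generate_pseudoalignments(
    annotation: TranscriptAnnotation,
    true_counts: pd.Series,
    multimap_rate: float = 0.0,
    seed: int = 1,
) -> list[tuple[str, list[str]]]:
    """Read -> candidate-transcript records exercising the 1/n assignment rule.

    Emits one record per read (total = sum of true_counts). With probability
    multimap_rate a read lists its true transcript plus 1-2 decoys drawn
    from the other annotated transcripts.
    """
    if not 0.0 <= multimap_rate <= 1.0:
        raise ValueError("multimap_rate must be in [0, 1]")
    if (true_counts < 0).any():
        raise ValueError("negative counts")
    rng = np.random.default_rng(seed)
    all_tx = list(annotation.transcript_ids)
    records: list[tuple[str, list[str]]] = []
    read_no = 0
    for tx, count in true_counts.items():
        if tx not in annotation.table.index:
            raise KeyError(f"transcript {tx!r} not in the annotation")
        for _ in range(int(round(count))):
            read_no += 1
            read_id = f"r{read_no:07d}"
            if len(all_tx) > 1 and rng.random() < multimap_rate:
                n_decoys = int(rng.integers(1, 3))  # 1 or 2 decoys -> 2-3 candidates
                others = [t for t in all_tx if t != tx]
                decoys = list(rng.choice(others, size=min(n_decoys, len(others)), replace=False))
                records.append((read_id, [tx] + decoys))
            else:
                records.append((read_id, [tx]))
    return records
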