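"""End-to-end orchestration: config, stage order, outputs and the manifest.

Stage order mirrors the analysis: quantify/load -> expression filter ->
log transform -> double-center + SVD -> gene-PC alignment -> signature
(fold changes, clustering, GSEA) -> pairwise fits. A synthetic mode first
invokes the generator and then scores planted-gene recovery against the
recorded ground truth.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from . import pca, quantify, signature as sig, synthetic
from .matrix import ExpressionMatrix
from .pairwise import tls_fit

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    out_dir: str = "txsig_out"
    synthetic: bool = False
    seed: int | None = None
    # file inputs (ignored in synthetic mode)
    matrix_path: str | None = None
    design_path: str | None = None
    matrix_unit: str = "TPM"
    # stage parameters
    filter_unit: str = "TPM"
    filter_threshold: float = 1.0
    log_transform: bool = True
    z_threshold: float = pca.Z_THRESHOLD
    r_threshold: float = pca.R_THRESHOLD
    z_mode: str = "pooled"
    cluster_k: int = 10
    cluster_linkage: str = "average"
    gsea_permutations: int = 1000
    # synthetic-mode generator parameters
    n_genes: int = 2000
    n_up: int = 50
    n_down: int = 50
    effect_size: float = 1.0
    noise_sd: float = 0.3
    reversal_coefficient: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required (stochastic stages refuse to run without one)")
        if not self.synthetic:
            for name in ("matrix_path", "design_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} is required unless synthetic=True")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class RunManifest:
    version: str
    config_hash: str
    started: float
    finished: float
    outputs: dict[str, str]  # filename -> sha256
    summary: dict
    n_warnings: int

    def write(self, path) -> None:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        with open(tmp, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, path)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages, writing TSV outputs and a JSON manifest."""
    config.validate()
    started = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    summary: dict = {}

    def save_matrix(m: ExpressionMatrix, name: str) -> None:
        p = out / name
        tio.write_expression_tsv(m, p)
        outputs[name] = p

    def save_table(df: pd.DataFrame, name: str, index: bool = False) -> None:
        p = out / name
        tio.write_table_tsv(df, p, index=index)
        outputs[name] = p

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        truth = None
        if config.synthetic:
            design = synthetic.DesignSpec(n_genes=config.n_genes)
            planted = synthetic.default_signature(
                design,
                n_up=config.n_up,
                n_down=config.n_down,
                effect_size=config.effect_size,
                reversal_coefficient=dict(config.reversal_coefficient),
            )
            matrix, truth = synthetic.generate_multimuscle(
                design, planted, noise_sd=config.noise_sd, seed=config.seed
            )
            tio.write_design_tsv(matrix.design, out / "design.tsv")
            outputs["design.tsv"] = out / "design.tsv"
            save_matrix(matrix, "tpm.tsv")
            truth_df = pd.DataFrame(
                {
                    "gene_id": sorted(truth.up_genes) + sorted(truth.down_genes),
                    "direction": [1] * len(truth.up_genes) + [-1] * len(truth.down_genes),
                }
            )
            save_table(truth_df, "truth.tsv")
        else:
            design_table = tio.read_design_tsv(config.design_path)
            matrix = tio.read_expression_tsv(
                config.matrix_path, unit=config.matrix_unit, design=design_table
            )

        filtered = quantify.expression_filter(
            matrix, threshold=config.filter_threshold, unit=config.filter_unit
        )
        summary["n_genes_after_filter"] = int(filtered.shape[0])
        logm = quantify.log_transform(filtered) if config.log_transform else filtered
        centered = pca.double_center(logm)
        decomp = pca.svd_decompose(centered)
        save_table(decomp.pc_coordinates(), "pc_coordinates.tsv", index=True)
        save_table(
            pd.DataFrame(
                {"pc": np.arange(1, decomp.n_pcs + 1), "d": decomp.d, "lambda": decomp.lam}
            ),
            "variance_fractions.tsv",
        )
        align = pca.alignment_table(
            decomp, config.z_threshold, config.r_threshold, z_mode=config.z_mode
        )
        save_table(align.table, "alignment.tsv")
        summary["variance_fractions"] = [float(x) for x in decomp.lam[:6]]

        if config.synthetic:
            aging_pc = pca.find_condition_pc(decomp, matrix.design, "10mCON", "30mCON")
            summary["aging_pc"] = aging_pc
            sets = pca.aligned_genes(
                decomp, aging_pc, config.z_threshold, config.r_threshold, z_mode=config.z_mode
            )
            called = sets.all_signed
            planted_here = truth.planted & set(map(str, decomp.gene_ids))
            nulls = set(map(str, decomp.gene_ids)) - truth.planted
            tp = len(called & planted_here)
            fp = len(called & nulls)
            sensitivity = tp / len(planted_here) if planted_here else float("nan")
            fpr = fp / len(nulls) if nulls else float("nan")
            summary["planted_sensitivity"] = sensitivity
            summary["false_positive_rate"] = fpr
            summary["recovery_pass"] = bool(sensitivity >= 0.9 and fpr <= 0.05)

            # per-muscle aging and drug contrasts, pairwise fits, reversal GSEA
            lfc = {}
            for m in synthetic.MUSCLES:
                lfc[f"{m}_aging"] = quantify.log_fold_changes(
                    filtered, (f"{m}:30mCON", f"{m}:10mCON")
                )
                lfc[f"{m}_drug"] = quantify.log_fold_changes(
                    filtered, (f"{m}:30mRM", f"{m}:30mCON")
                )
            profiles = pd.DataFrame(lfc)
            save_table(profiles, "fold_changes.tsv", index=True)
            signed_profiles = profiles.loc[sorted(called & set(profiles.index))]
            if len(signed_profiles) >= config.cluster_k:
                clusters = sig.cluster_profiles(
                    signed_profiles, k=config.cluster_k, method=config.cluster_linkage
                )
                save_table(clusters.reset_index(), "clusters.tsv")
            drug_rank = profiles[[f"{m}_drug" for m in synthetic.MUSCLES]].mean(axis=1)
            screen = sig.reversal_screen(
                {"planted_up": set(truth.up_genes), "planted_down": set(truth.down_genes)},
                drug_rank,
                n_permutations=config.gsea_permutations,
                seed=config.seed,
            )
            summary["gsea"] = {
                k: {"es": r.es, "nes": r.nes, "fdr": r.fdr} for k, r in screen.items()
            }
            fits = []
            muscles = synthetic.MUSCLES
            for i, a in enumerate(muscles):
                for b in muscles[i + 1 :]:
                    f = tls_fit(profiles[f"{a}_aging"], profiles[f"{b}_aging"])
                    fits.append((f"{a}_vs_{b}_aging", f.slope, f.intercept, f.r, f.n))
            save_table(
                pd.DataFrame(fits, columns=["pair", "slope", "intercept", "r", "n"]),
                "pairwise_fits.tsv",
            )

    n_warnings = len(caught)
    manifest = RunManifest(
        version=__version__,
        config_hash=config.config_hash(),
        started=started,
        finished=time.time(),
        outputs={name: _sha256(p) for name, p in outputs.items()},
        summary=summary,
        n_warnings=n_warnings,
    )
    manifest.write(out / "manifest.json")
    return manifest
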