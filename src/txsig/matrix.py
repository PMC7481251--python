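"""Expression-matrix container and transcript annotation.

The central in-memory object is :class:`ExpressionMatrix`: a feature x sample
pandas DataFrame tagged with the unit of its values (raw counts, CPM, TPM or
log2(TPM+1)) and an optional per-sample design table mapping each sample to a
(muscle, condition) group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_UNITS = ("counts", "CPM", "TPM", "logTPM")

#: relative tolerance for the "TPM columns sum to 1e6" invariant
TPM_COLSUM_RTOL = 1e-6


@dataclass
class ExpressionMatrix:
    """Feature x sample expression values with a unit tag and sample design.

    Parameters
    ----------
    values
        DataFrame, index = feature ids (transcripts or genes), columns =
        sample ids, all finite and non-negative (logTPM may contain zeros
        but never negatives because of the +1 pseudocount).
    unit
        One of ``counts``, ``CPM``, ``TPM``, ``logTPM``.
    design
        Optional DataFrame indexed by sample id with columns ``muscle`` and
        ``condition``. Group = (muscle, condition).
    """

    values: pd.DataFrame
    unit: str
    design: pd.DataFrame | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.design is not None:
            missing = [s for s in self.values.columns if s not in self.design.index]
            if missing:
                raise ValueError(f"samples absent from design table: {missing[:5]}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def group_labels(self) -> pd.Series:
        """Per-sample group label '<muscle>:<condition>' from the design."""
        if self.design is None:
            raise ValueError("no design table attached")
        d = self.design.loc[self.values.columns]
        return d["muscle"].astype(str) + ":" + d["condition"].astype(str)

    def samples_in_group(self, group: str) -> list[str]:
        """Sample ids whose group label (muscle:condition) equals `group`.

        A bare condition label (no colon) selects all muscles with that
        condition.
        """
        labels = self.group_labels()
        if ":" in group:
            sel = labels == group
        else:
            d = self.design.loc[self.values.columns]
            sel = d["condition"].astype(str) == group
        samples = list(labels.index[sel])
        if not samples:
            raise KeyError(f"group {group!r} matches no samples in the design")
        return samples

    def with_values(self, values: pd.DataFrame, unit: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, unit or self.unit, self.design, dict(self.flags))

    def check_tpm_sums(self) -> None:
        """Raise if unit is TPM but some column does not sum to 1e6."""
        if self.unit != "TPM":
            return
        sums = self.values.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1e6, rtol=TPM_COLSUM_RTOL):
            bad = self.values.columns[~np.isclose(sums, 1e6, rtol=TPM_COLSUM_RTOL)]
            raise ValueError(f"TPM columns not summing to 1e6: {list(bad)[:5]}")


@dataclass
class TranscriptAnnotation:
    """Transcript id -> (gene id, length in nucleotides)."""

    table: pd.DataFrame  # columns: transcript_id, gene_id, length

    def __post_init__(self) -> None:
        required = {"transcript_id", "gene_id", "length"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        if self.table["transcript_id"].duplicated().any():
            dups = self.table.loc[self.table["transcript_id"].duplicated(), "transcript_id"]
            raise ValueError(f"duplicate transcript ids: {dups.tolist()[:5]}")
        if (self.table["length"] <= 0).any():
            raise ValueError("transcript lengths must be positive")
        self.table = self.table.set_index("transcript_id", drop=False)

    @property
    def transcript_ids(self) -> pd.Index:
        return self.table.index

    def lengths(self, transcript_ids) -> np.ndarray:
        missing = [t for t in transcript_ids if t not in self.table.index]
        if missing:
            raise KeyError(f"transcripts without annotation: {missing[:5]}")
        return self.table.loc[transcript_ids, "length"].to_numpy(dtype=float)

    def gene_of(self, transcript_ids) -> pd.Series:
        missing = [t for t in transcript_ids if t not in self.table.index]
        if missing:
            raise KeyError(f"transcripts without gene mapping: {missing[:5]}")
        return self.table.loc[transcript_ids, "gene_id"]
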