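"""Core in-memory containers shared across the pipeline.

All matrices are pandas DataFrames: probes on rows (indexed by probe id),
samples on columns (sample ids matching the sample sheet).  M values are
log2(test/reference) ratios; A values are mean log2 intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_SHEET_COLUMNS = ("sample_id", "donor_id", "platform", "replicate_index")
ANNOTATION_COLUMNS = (
    "probe_id",
    "gene_id",
    "Dist3",
    "Dist5",
    "TranscriptSize",
    "GeneSize",
    "GCpercent",
)


class FormatError(ValueError):
    """A file or table does not conform to its expected layout."""


@dataclass
class IntensityArray:
    """One hybridization's two-channel raw signals.

    ``data`` holds one row per on-array probe occurrence (probe ids may
    repeat for on-array duplicates) with columns ``probe_id``, ``gene_id``,
    ``red_signal``, ``green_signal``.  Signals are median fluorescence and
    must be strictly positive so that log2 ratios are defined.
    """

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_id", "red_signal", "green_signal"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"intensity table missing columns: {sorted(missing)}")
        for col in ("red_signal", "green_signal"):
            bad = np.flatnonzero(~(self.data[col].to_numpy(dtype=float) > 0))
            if bad.size:
                raise ValueError(
                    f"non-positive {col} in sample {self.sample_id!r} "
                    f"at row {int(bad[0])}"
                )

    @property
    def n_probes(self) -> int:
        return len(self.data)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check the sample sheet invariants and return it unchanged."""
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    dup = sheet["sample_id"][sheet["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id in sheet: {dup.iloc[0]!r}")
    return sheet


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check probe-annotation invariants and return the table unchanged."""
    missing = set(ANNOTATION_COLUMNS) - set(annotation.columns)
    if missing:
        raise FormatError(f"annotation missing columns: {sorted(missing)}")
    gc = annotation["GCpercent"].to_numpy(dtype=float)
    if ((gc < 0) | (gc > 100)).any():
        row = int(np.flatnonzero((gc < 0) | (gc > 100))[0])
        raise ValueError(f"GCpercent outside [0, 100] at row {row}")
    for col in ("Dist3", "Dist5", "TranscriptSize", "GeneSize"):
        vals = annotation[col].to_numpy(dtype=float)
        if (vals < 0).any():
            row = int(np.flatnonzero(vals < 0)[0])
            raise ValueError(f"negative {col} at row {row}")
    return annotation


@dataclass
class ExpressionMatrix:
    """Normalized expression: unique probes x samples, with metadata.

    ``M`` and ``A`` share index (probe ids, unique after duplicate
    averaging) and columns (sample ids, ordered as in ``samples``).
    ``gene_map`` maps probe id -> gene id.
    """

    M: pd.DataFrame
    A: pd.DataFrame
    samples: pd.DataFrame
    gene_map: pd.Series

    def __post_init__(self) -> None:
        if self.M.index.has_duplicates:
            raise ValueError("ExpressionMatrix probe ids must be unique")
        if list(self.M.columns) != list(self.samples["sample_id"]):
            raise ValueError("matrix column order must match the sample sheet")
        if self.M.isna().to_numpy().any():
            raise ValueError("ExpressionMatrix must not contain missing values")

    @property
    def probe_ids(self) -> pd.Index:
        return self.M.index

    def platform_samples(self, platform: str) -> list[str]:
        mask = self.samples["platform"] == platform
        return list(self.samples.loc[mask, "sample_id"])


@dataclass
class ConcordanceResult:
    """Per-platform replicate concordance summary.

    ``sn_ratio`` is the mean within-donor Pearson correlation divided by
    the mean across-donor correlation; values above 1 mean individual
    identity is detectable above technical noise.
    """

    platform: str
    mean_within_donor_correlation: float
    mean_across_donor_correlation: float
    sn_ratio: float
    n_within_pairs: int
    n_across_pairs: int


@dataclass
class PcaResult:
    """Sample scores and explained-variance fractions from PCA of M values."""

    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    n_components: int


@dataclass
class GroundTruth:
    """Latent parameters of a simulated experiment (for validation only).

    All effects are additive on the log2 (M value) scale.
    """

    mu: pd.Series  # probe baselines, indexed by probe_id
    beta: pd.DataFrame  # probes x donors donor effects
    delta: pd.DataFrame  # probes x platforms platform offsets
    sigma: pd.DataFrame  # probes x platforms replicate noise sds
    duplicated_probes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for df in (self.beta, self.delta, self.sigma):
            if not df.index.equals(self.mu.index):
                raise ValueError("ground-truth tables must share the probe index")
        if (self.sigma.to_numpy() < 0).any():
            raise ValueError("noise sds must be non-negative")
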