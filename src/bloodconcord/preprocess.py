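"""Normalization chain: M-A conversion, within-array loess, across-array
quantile normalization, duplicate-probe averaging, optional variance filter.

The stage order is fixed: per-array M/A computation, loess normalization of
M against A within each array, quantile normalization of M across arrays,
then averaging of on-array duplicate probes (and, optionally, a variance
filter keeping the most variable probes).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .types import ExpressionMatrix, IntensityArray, validate_sample_sheet

DEFAULT_SPAN = 0.3
LOESS_ITERATIONS = 4
_LOESS_DELTA_FRAC = 0.01  # interpolation window as a fraction of range(A)


def compute_ma(array: IntensityArray) -> pd.DataFrame:
    """Convert two-channel signals to M (log2 ratio) and A (mean log2).

    M = log2(red) - log2(green); A = (log2(red) + log2(green)) / 2.
    """
    red = np.log2(array.data["red_signal"].to_numpy(dtype=float))
    green = np.log2(array.data["green_signal"].to_numpy(dtype=float))
    return pd.DataFrame({
        "probe_id": array.data["probe_id"].to_numpy(),
        "gene_id": array.data["gene_id"].to_numpy(),
        "M": red - green,
        "A": (red + green) / 2.0,
    })


def loess_normalize_array(
    M: np.ndarray,
    A: np.ndarray,
    span: float = DEFAULT_SPAN,
    iterations: int = LOESS_ITERATIONS,
) -> np.ndarray:
    """Remove the intensity-dependent trend of M on A within one array.

    Fits a robust locally weighted linear regression (tricube weights,
    ``span`` fraction of points per local fit, ``iterations`` robustifying
    passes) and returns the residuals M - fit(A).

    Robustification needs residual noise to estimate outlier weights
    from; when the initial fit already explains >99% of the variance of M
    (noiseless or calibration-type input) the residual scale is pure
    lack-of-fit, the weights degenerate, and the robust passes are
    skipped.
    """
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    if M.shape != A.shape:
        raise ValueError("M and A must have the same length")
    if M.size < 10:
        raise ValueError(f"need at least 10 probes for loess, got {M.size}")
    if np.ptp(A) == 0:
        warnings.warn("constant A values: subtracting mean(M) instead of loess fit")
        return M - M.mean()
    delta = _LOESS_DELTA_FRAC * np.ptp(A)
    fit = lowess(M, A, frac=span, it=0, delta=delta, return_sorted=False)
    resid = M - fit
    if iterations > 0 and M.var() > 0 and resid.var() > 0.01 * M.var():
        fit = lowess(M, A, frac=span, it=iterations, delta=delta,
                     return_sorted=False)
        resid = M - fit
    return resid


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common reference distribution.

    The reference is the row-mean of the column-sorted matrix; each
    column's sorted values are replaced by it.  Ties within a column
    receive the mean of the reference values their positions span, so
    tied inputs stay tied.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile normalization requires a complete matrix")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(reference)
        ranked[order] = reference
        # tied values share the mean of the reference quantiles they span
        uniq, inverse, counts = np.unique(
            col, return_inverse=True, return_counts=True
        )
        if uniq.size < col.size:
            sums = np.bincount(inverse, weights=ranked)
            ranked = (sums / counts)[inverse]
        out[:, j] = ranked
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def average_duplicates(
    matrix: pd.DataFrame, probe_ids: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Average rows sharing a probe id; output indexed by unique probe id."""
    probe_ids = np.asarray(probe_ids)
    if len(probe_ids) != len(matrix):
        raise ValueError("probe_ids length must match matrix rows")
    grouped = matrix.groupby(pd.Index(probe_ids, name="probe_id"), sort=True).mean()
    return grouped


def variance_filter(matrix: pd.DataFrame, keep_fraction: float) -> pd.DataFrame:
    """Keep the top ``keep_fraction`` of probes by variance across samples.

    Ranking is by variance descending; boundary ties resolve in favor of
    the lexicographically smaller probe id.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    if keep_fraction == 1.0:
        return matrix
    variances = matrix.var(axis=1, ddof=1)
    # deterministic: variance descending, probe id ascending on ties
    ranked = sorted(variances.items(), key=lambda kv: (-kv[1], kv[0]))
    n_keep = int(np.ceil(keep_fraction * len(ranked)))
    keep = [probe for probe, _ in ranked[:n_keep]]
    return matrix.loc[sorted(keep)]


def normalize_experiment(
    arrays: list[IntensityArray],
    sheet: pd.DataFrame,
    span: float = DEFAULT_SPAN,
    keep_fraction: float | None = None,
) -> ExpressionMatrix:
    """Run the full chain on a set of arrays and return the matrix.

    All arrays must present the same probe occurrence sequence (same
    physical design).  ``keep_fraction`` enables the optional variance
    filter; ``None`` keeps every probe.
    """
    validate_sample_sheet(sheet)
    by_id = {a.sample_id: a for a in arrays}
    missing = [s for s in sheet["sample_id"] if s not in by_id]
    if missing:
        raise ValueError(f"sample sheet references missing arrays: {missing[:3]}")
    ordered = [by_id[s] for s in sheet["sample_id"]]

    first = compute_ma(ordered[0])
    probe_ids = first["probe_id"].to_numpy()
    gene_ids = first["gene_id"].to_numpy()

    m_cols, a_cols = {}, {}
    for arr in ordered:
        ma = compute_ma(arr)
        if not np.array_equal(ma["probe_id"].to_numpy(), probe_ids):
            raise ValueError(
                f"array {arr.sample_id!r} probe layout differs from the first array"
            )
        m_cols[arr.sample_id] = loess_normalize_array(
            ma["M"].to_numpy(), ma["A"].to_numpy(), span=span
        )
        a_cols[arr.sample_id] = ma["A"].to_numpy()

    m_raw = pd.DataFrame(m_cols)
    a_raw = pd.DataFrame(a_cols)
    m_norm = quantile_normalize(m_raw)

    m_avg = average_duplicates(m_norm, probe_ids)
    a_avg = average_duplicates(a_raw, probe_ids)
    gene_map = (
        pd.Series(gene_ids, index=pd.Index(probe_ids, name="probe_id"))
        .groupby(level=0)
        .first()
        .rename("gene_id")
    )
    if keep_fraction is not None:
        m_avg = variance_filter(m_avg, keep_fraction)
        a_avg = a_avg.loc[m_avg.index]
        gene_map = gene_map.loc[m_avg.index]
    return ExpressionMatrix(M=m_avg, A=a_avg, samples=sheet, gene_map=gene_map)
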