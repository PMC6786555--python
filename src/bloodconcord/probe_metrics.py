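"""Per-probe variability metrics and their correlations with probe properties.

Within a platform each probe gets: Var, the mean over donors of the
replicate variance of M; FD, the mean over donors of the mean absolute
pairwise replicate difference (log2 units); a one-way ANOVA p-value for
donor differences; and meanM/meanA over the platform's samples.  Across
two platforms each probe gets a paired t-test p-value over donors of the
per-donor platform difference.  All metrics are then Pearson-correlated
with probe physical properties (distances to transcript ends, transcript
and gene size, GC percent) plus meanM and meanA, with the standard
t-based two-sided p-value and a significance flag at p < 0.01.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix

PROBE_PROPERTIES = ("Dist3", "Dist5", "TranscriptSize", "GeneSize", "GCpercent")
SIGNIFICANCE_ALPHA = 0.01


def _donor_groups(
    sheet: pd.DataFrame, platform: str, min_replicates: int = 2
) -> dict[str, list[str]]:
    sub = sheet[sheet["platform"] == platform]
    if sub.empty:
        raise ValueError(f"no samples for platform {platform!r}")
    groups = {
        donor: list(block["sample_id"])
        for donor, block in sub.groupby("donor_id", sort=True)
    }
    dropped = [d for d, cols in groups.items() if len(cols) < min_replicates]
    if dropped:
        warnings.warn(
            f"platform {platform!r}: dropping donors with <{min_replicates} "
            f"replicates: {dropped}"
        )
        groups = {d: c for d, c in groups.items() if d not in dropped}
    if len(groups) < 2:
        raise ValueError(
            f"platform {platform!r}: fewer than 2 donors with replicates"
        )
    return groups


def _anova_pvalues(blocks: list[np.ndarray]) -> np.ndarray:
    """Vectorized one-way ANOVA across donor groups, per probe row.

    Degenerate rows: zero within- and between-group variance -> p=1;
    zero within- but positive between-group variance -> p=0.
    """
    ns = np.array([b.shape[1] for b in blocks], dtype=float)
    total_n = ns.sum()
    k = len(blocks)
    group_means = np.column_stack([b.mean(axis=1) for b in blocks])
    grand = (group_means * ns).sum(axis=1) / total_n
    ssb = (ns * (group_means - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.zeros_like(ssb)
    for b, m in zip(blocks, group_means.T):
        ssw += ((b - m[:, None]) ** 2).sum(axis=1)
    dfb, dfw = k - 1, total_n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(f, dfb, dfw)
    zero_w = ssw <= 0
    p[zero_w & (ssb <= 0)] = 1.0
    p[zero_w & (ssb > 0)] = 0.0
    return p


def within_platform_metrics(
    matrix: ExpressionMatrix, platform: str, pval_method: str = "anova"
) -> pd.DataFrame:
    """Per-probe Var, pval, FD, meanM, meanA for one platform.

    ``pval_method='anova'`` (default) tests donor differences by one-way
    ANOVA over replicate groups; ``'ttest'`` instead tests mean M against
    0 with a one-sample t-test over all the platform's samples.  Donors
    with a single replicate are dropped from Var/FD/pval with a warning;
    meanM and meanA use every sample of the platform.
    """
    groups = _donor_groups(matrix.samples, platform)
    blocks = [matrix.M[cols].to_numpy(dtype=float) for cols in groups.values()]

    var = np.mean([b.var(axis=1, ddof=1) for b in blocks], axis=0)
    fds = []
    for b in blocks:
        k = b.shape[1]
        pair_abs = [np.abs(b[:, i] - b[:, j]) for i, j in combinations(range(k), 2)]
        fds.append(np.mean(pair_abs, axis=0))
    fd = np.mean(fds, axis=0)
    all_cols = matrix.platform_samples(platform)
    if pval_method == "anova":
        pval = _anova_pvalues(blocks)
    elif pval_method == "ttest":
        pval = stats.ttest_1samp(
            matrix.M[all_cols].to_numpy(dtype=float), 0.0, axis=1
        ).pvalue
    else:
        raise ValueError(f"unknown pval_method {pval_method!r}")
    return pd.DataFrame(
        {
            "Var": var,
            "pval": pval,
            "FD": fd,
            "meanM": matrix.M[all_cols].mean(axis=1).to_numpy(),
            "meanA": matrix.A[all_cols].mean(axis=1).to_numpy(),
        },
        index=matrix.probe_ids,
    )


def cross_platform_test(
    matrix: ExpressionMatrix,
    platform_a: str,
    platform_b: str,
    method: str = "paired",
) -> pd.DataFrame:
    """Per-probe test of platform differences across the same donors.

    Replicates are first averaged to one M per (donor, platform); the
    default is a paired two-sided t-test over donors of the difference
    a - b.  Rows with zero-variance differences: all-zero -> p=1,
    otherwise p=0 (t diverges).  ``method='welch'`` runs an unpaired
    Welch t-test over the per-donor means instead.
    """
    sheet = matrix.samples

    def donor_means(platform: str) -> pd.DataFrame:
        sub = sheet[sheet["platform"] == platform]
        cols = {
            donor: matrix.M[list(block["sample_id"])].mean(axis=1)
            for donor, block in sub.groupby("donor_id", sort=True)
        }
        return pd.DataFrame(cols)

    ma, mb = donor_means(platform_a), donor_means(platform_b)
    common = [d for d in ma.columns if d in mb.columns]
    if len(common) < 3:
        raise ValueError(
            f"need >=3 donors common to {platform_a!r} and {platform_b!r}, "
            f"got {len(common)}"
        )
    a = ma[common].to_numpy(dtype=float)
    b = mb[common].to_numpy(dtype=float)
    n = len(common)
    if method == "paired":
        d = a - b
        mean = d.mean(axis=1)
        sd = d.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), n - 1)
        zero_sd = sd == 0
        p[zero_sd & (mean == 0)] = 1.0
        p[zero_sd & (mean != 0)] = 0.0
        mean_diff = mean
    elif method == "welch":
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.nan_to_num(p, nan=1.0)
        mean_diff = a.mean(axis=1) - b.mean(axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(
        {"cross_pval": p, "mean_diff": mean_diff}, index=matrix.probe_ids
    )


def pearson_with_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the t-transform two-sided p-value on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), n - 2))


def correlate_with_properties(
    metrics: pd.DataFrame,
    annotation: pd.DataFrame,
    measures: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each variability measure with each property.

    Properties are the annotation's physical columns plus the platform's
    meanM and meanA.  Probes missing annotation are dropped (count in the
    ``n`` column); constant inputs are flagged as undefined.
    """
    ann = annotation.set_index("probe_id")
    joined = metrics.join(ann, how="inner")
    if measures is None:
        measures = [
            c for c in metrics.columns
            if c not in {"meanM", "meanA", "mean_diff"}
        ]
    properties = [p for p in PROBE_PROPERTIES if p in joined.columns]
    properties += [p for p in ("meanM", "meanA") if p in joined.columns]
    rows = []
    for measure in measures:
        for prop in properties:
            sub = joined[[measure, prop]].dropna()
            r, p = pearson_with_pvalue(sub[measure], sub[prop])
            rows.append({
                "measure": measure,
                "property": prop,
                "r": r,
                "p": p,
                "significant": bool(p < SIGNIFICANCE_ALPHA)
                if not np.isnan(p) else False,
                "undefined": bool(np.isnan(r)),
                "n": len(sub),
            })
    return pd.DataFrame(rows)


def plot_variance_vs_gc(
    metrics: pd.DataFrame, annotation: pd.DataFrame, path: str | None = None
) -> tuple[object, float, float]:
    """Scatter of probe Var against GC percent with an OLS line.

    Returns (figure, slope, intercept); slope units are log2^2 per GC%.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    joined = metrics.join(annotation.set_index("probe_id"), how="inner")
    joined = joined[["Var", "GCpercent"]].dropna()
    if joined.empty:
        raise ValueError("no probes with both Var and GCpercent")
    x = joined["GCpercent"].to_numpy(dtype=float)
    y = joined["Var"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        slope, intercept = 0.0, float(y.mean())
    else:
        slope, intercept = np.polyfit(x, y, 1)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(x, y, s=8, alpha=0.4, color="steelblue")
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, slope * xs + intercept, color="red", linewidth=1.5)
    ax.set_xlabel("GC percent")
    ax.set_ylabel("probe Var (log2$^2$)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig, float(slope), float(intercept)
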