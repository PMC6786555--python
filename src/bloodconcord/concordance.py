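"""Replicate concordance: within/across-donor correlations, S/N, and PCA.

The headline statistic is the signal-to-noise ratio of a platform: the
mean Pearson correlation of probe M values between technical replicates
of the same donor, divided by the mean correlation between samples from
different donors on the same platform.  Ratios above 1 mean individual
expression differences survive the platform's technical noise.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .types import ConcordanceResult, ExpressionMatrix, PcaResult


def pairwise_sample_correlations(
    matrix: ExpressionMatrix, platform: str, method: str = "pearson"
) -> pd.DataFrame:
    """Correlation (over probes) between every pair of a platform's samples."""
    samples = matrix.platform_samples(platform)
    if len(samples) < 2:
        raise ValueError(f"platform {platform!r} has fewer than 2 samples")
    sub = matrix.M[samples]
    sds = sub.std(axis=0, ddof=1)
    flat = sds[sds == 0]
    if len(flat):
        raise ValueError(f"zero-variance sample: {flat.index[0]!r}")
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"unknown correlation method {method!r}")
    return sub.corr(method=method)


def sn_from_means(mean_within: float, mean_across: float) -> float:
    """S/N ratio from the two mean correlations."""
    if mean_across == 0:
        raise ValueError("mean across-donor correlation is zero")
    return mean_within / mean_across


def signal_to_noise(
    corr: pd.DataFrame, sheet: pd.DataFrame, platform: str
) -> ConcordanceResult:
    """Summarize a platform's correlation matrix into the S/N ratio.

    Within pairs share a donor; across pairs do not (both restricted to
    the platform).  The ratio is the ratio of the two pair means.
    """
    sub = sheet[sheet["platform"] == platform]
    donor = dict(zip(sub["sample_id"], sub["donor_id"]))
    samples = [s for s in corr.index if s in donor]
    within, across = [], []
    for a, b in combinations(samples, 2):
        (within if donor[a] == donor[b] else across).append(corr.loc[a, b])
    if not within:
        raise ValueError(f"platform {platform!r}: no within-donor sample pairs")
    if not across:
        raise ValueError(f"platform {platform!r}: no across-donor sample pairs")
    mean_within = float(np.mean(within))
    mean_across = float(np.mean(across))
    return ConcordanceResult(
        platform=platform,
        mean_within_donor_correlation=mean_within,
        mean_across_donor_correlation=mean_across,
        sn_ratio=sn_from_means(mean_within, mean_across),
        n_within_pairs=len(within),
        n_across_pairs=len(across),
    )


def platform_concordance(
    matrix: ExpressionMatrix, platform: str, method: str = "pearson"
) -> ConcordanceResult:
    """Convenience: correlations plus S/N for one platform."""
    corr = pairwise_sample_correlations(matrix, platform, method=method)
    return signal_to_noise(corr, matrix.samples, platform)


def concordance_table(
    matrix: ExpressionMatrix, method: str = "pearson"
) -> pd.DataFrame:
    """S/N summary for every platform in the sample sheet."""
    rows = []
    for platform in matrix.samples["platform"].unique():
        r = platform_concordance(matrix, platform, method=method)
        rows.append({
            "platform": r.platform,
            "mean_within_donor_correlation": r.mean_within_donor_correlation,
            "mean_across_donor_correlation": r.mean_across_donor_correlation,
            "sn_ratio": r.sn_ratio,
            "n_within_pairs": r.n_within_pairs,
            "n_across_pairs": r.n_across_pairs,
        })
    return pd.DataFrame(rows)


def pca_samples(matrix: ExpressionMatrix, n_components: int = 2) -> PcaResult:
    """PCA of samples in probe space.

    Samples are observations, probes variables; each probe is centered
    across samples but not scaled (M values already share a scale after
    quantile normalization).  Scores come from the SVD of the centered
    matrix.
    """
    X = matrix.M.to_numpy(dtype=float).T  # samples x probes
    max_comp = min(X.shape[0], X.shape[1])
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_probes)={max_comp}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PcaResult(
        scores=pd.DataFrame(
            scores,
            index=matrix.M.columns,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_components=n_components,
    )


def plot_pca(
    result: PcaResult, sheet: pd.DataFrame, path: str | None = None
):
    """Scatter of PC1 vs PC2, colored by donor, marker per platform."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    meta = sheet.set_index("sample_id").loc[result.scores.index]
    donors = sorted(meta["donor_id"].unique())
    platforms = sorted(meta["platform"].unique())
    cmap = plt.get_cmap("tab10")
    markers = ["o", "s", "^", "D", "v", "P", "X"]
    for qi, plat in enumerate(platforms):
        for di, donor in enumerate(donors):
            mask = (meta["platform"] == plat) & (meta["donor_id"] == donor)
            if not mask.any():
                continue
            pts = result.scores[mask.to_numpy()]
            ax.scatter(
                pts.iloc[:, 0], pts.iloc[:, 1],
                color=cmap(di % 10), marker=markers[qi % len(markers)],
                s=35, edgecolor="black", linewidth=0.3,
                label=plat if di == 0 else None,
            )
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}% var)")
    ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}% var)")
    ax.legend(title="platform", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
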