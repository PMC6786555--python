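"""Gene selection and local over-representation testing.

Two selection rules feed the enrichment step: the genes with the top
fraction of mean within-individual variance in a platform, and the genes
measured relatively higher in one platform than another (paired test
p < alpha, split by sign).  Over-representation of a gene set among the
selected genes is scored with a one-sided hypergeometric tail p-value and
Benjamini-Hochberg FDR across sets.  This is a plain hypergeometric test,
not DAVID's modified Fisher (EASE) score, so FDRs from annotation servers
are not expected to match numerically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def collapse_probe_variance(
    metrics: pd.DataFrame, gene_map: pd.Series, collapse: str = "max"
) -> pd.Series:
    """Collapse per-probe Var to per-gene Var (max per gene by default)."""
    var = metrics["Var"]
    genes = gene_map.loc[var.index]
    grouped = var.groupby(genes.to_numpy())
    if collapse == "max":
        return grouped.max()
    if collapse == "mean":
        return grouped.mean()
    raise ValueError(f"unknown collapse {collapse!r}")


def select_top_variance_genes(
    metrics: pd.DataFrame,
    gene_map: pd.Series,
    fraction: float = 0.05,
    collapse: str = "max",
) -> list[str]:
    """Genes with the top ``fraction`` of within-individual variance.

    Probes collapse to genes (``collapse='max'``: the most variable probe
    represents the gene), genes rank by Var descending, and the top
    ceil(fraction * n_genes) are returned; boundary ties resolve to the
    lexicographically smaller gene id.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    gene_var = collapse_probe_variance(metrics, gene_map, collapse=collapse)
    ranked = sorted(gene_var.items(), key=lambda kv: (-kv[1], kv[0]))
    n_keep = int(np.ceil(fraction * len(ranked)))
    return [gene for gene, _ in ranked[:n_keep]]


def select_platform_higher_genes(
    cross: pd.DataFrame, gene_map: pd.Series, alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Split significant genes by the platform they are higher in.

    ``cross`` is the per-probe output of ``cross_platform_test`` for
    platforms (a, b).  A gene qualifies if any of its probes has
    p < alpha; the sign of that probe's mean difference decides the list
    (positive: higher in a, negative: higher in b).
    """
    sig = cross[cross["cross_pval"] < alpha]
    genes = gene_map.loc[sig.index]
    higher_a = sorted(set(genes[sig["mean_diff"] > 0]))
    higher_b = sorted(set(genes[sig["mean_diff"] < 0]))
    return higher_a, higher_b


def overrepresentation_test(
    selected: list[str] | set[str],
    universe: list[str] | set[str],
    sets: dict[str, dict],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set.

    For a universe of N genes of which K belong to the set and a
    selection of n genes with k overlapping, the one-sided p-value is
    P(X >= k) with X ~ Hypergeometric(N, K, n).  FDR is Benjamini-
    Hochberg across all tested sets; fold enrichment is
    (k/n) / (K/N).  Results are sorted by p-value.
    """
    universe = set(universe)
    selected = set(selected)
    if not universe:
        raise ValueError("empty universe")
    if not selected:
        raise ValueError("empty selection")
    if not selected <= universe:
        extra = sorted(selected - universe)[:3]
        raise ValueError(f"selected genes outside universe: {extra}")
    N, n = len(universe), len(selected)
    rows = []
    for name, spec in sets.items():
        in_universe = spec["genes"] & universe
        K = len(in_universe)
        k = len(in_universe & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if K else float("nan")
        rows.append({
            "set": name,
            "description": spec.get("description", ""),
            "universe_size": N,
            "set_in_universe": K,
            "selected_size": n,
            "overlap": k,
            "p": p,
            "fold_enrichment": fold,
        })
    result = pd.DataFrame(rows)
    if len(result):
        result["fdr"] = multipletests(result["p"], method="fdr_bh")[1]
        result = result.sort_values(
            ["p", "set"], kind="stable"
        ).reset_index(drop=True)
    return result
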