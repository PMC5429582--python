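"""Downstream expression analyses: QC, gene-set selections, clustering.

Slide (batch) effects are removed for PCA and clustering inputs by estimating
them jointly with condition effects per gene and subtracting the slide
component; the hypothesis-testing path does not use this matrix but keeps the
slide factor inside the linear model.  Gene-set selections follow the study's
thresholds: disease-specific genes by the overall moderated F at BH-adjusted
p < 0.1, an early-response set by nominal double-difference p < 0.2 at all of
4, 8 and 24 h, and per-time-point up/down counting at adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from polyqtc.expression.linmod import ContrastResult, DesignInfo, build_design

__all__ = [
    "DEThresholds",
    "remove_slide_effect",
    "pca_qc",
    "count_de_timecourse",
    "select_hd_specific",
    "select_early_response",
    "cluster_profiles",
    "plot_de_counts",
    "plot_pca",
    "plot_cluster_profiles",
]


@dataclass(frozen=True)
class DEThresholds:
    """Significance thresholds of the differential-expression analysis."""

    alpha_within: float = 0.05  # per-time-point adjusted p (DE counting)
    alpha_overall_hd: float = 0.1  # adjusted overall-F p (disease-specific set)
    alpha_early: float = 0.2  # nominal p at the early time points
    early_timepoints: tuple[float, ...] = (4.0, 8.0, 24.0)

    def __post_init__(self) -> None:
        for a in (self.alpha_within, self.alpha_overall_hd, self.alpha_early):
            if not 0 < a < 1:
                raise ValueError("thresholds must lie in (0, 1)")


def _slide_column_names(design: DesignInfo) -> list[str]:
    return [c for c in design.colnames if c.startswith("slide_")]


def remove_slide_effect(
    expr: pd.DataFrame, meta: pd.DataFrame, design: DesignInfo | None = None
) -> pd.DataFrame:
    """Subtract per-gene slide effects estimated jointly with condition effects.

    Least-squares fit of condition + slide per gene; only the slide component
    is removed, so per-condition means are preserved.  Raises if any slide
    level is confounded with (aliased to) the condition block.
    """
    design = design or build_design(meta)
    if design.dropped_slide_cols:
        raise ValueError(
            "slide factor confounded with condition; aliased levels: "
            f"{design.dropped_slide_cols}"
        )
    expr = expr[design.array_ids]
    x = design.matrix
    y = expr.to_numpy().T  # arrays x genes
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    slide_cols = [design.col_index(c) for c in _slide_column_names(design)]
    if not slide_cols:
        return expr.copy()
    slide_part = x[:, slide_cols] @ coef[slide_cols, :]
    corrected = (y - slide_part).T
    return pd.DataFrame(corrected, index=expr.index, columns=expr.columns)


def pca_qc(expr: pd.DataFrame, meta: pd.DataFrame | None = None):
    """Centered PCA over arrays; returns (scores, explained-variance fractions).

    Arrays are observations and genes features; each gene is centered across
    arrays.  Scores come back as a DataFrame (arrays x PCs) joined with the
    per-array metadata when provided.
    """
    x = expr.to_numpy().T  # arrays x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    k = min(scores.shape[1], 10)
    df = pd.DataFrame(
        scores[:, :k], index=expr.columns, columns=[f"PC{i+1}" for i in range(k)]
    )
    if meta is not None:
        df = df.join(meta)
    return df, explained[:k]


def count_de_timecourse(
    result: ContrastResult, thresholds: DEThresholds | None = None
) -> pd.DataFrame:
    """Per-time-point counts of up/down-regulated genes per contrast family.

    A gene counts at adjusted p < alpha_within, split by the sign of its
    log fold change; families are the control ("C") and disease ("HD")
    within-line contrasts and the disease-specific double difference ("DD").
    """
    thresholds = thresholds or DEThresholds()
    rows = []
    for fam, tab in result.per_timepoint.items():
        for t_h, sub in tab.groupby("time_h"):
            sig = sub[sub["adj_p"] < thresholds.alpha_within]
            rows.append(
                {
                    "family": fam,
                    "time_h": float(t_h),
                    "n_up": int((sig["logFC"] > 0).sum()),
                    "n_down": int((sig["logFC"] < 0).sum()),
                }
            )
    return pd.DataFrame(rows).sort_values(["family", "time_h"]).reset_index(drop=True)


def select_hd_specific(
    result: ContrastResult, thresholds: DEThresholds | None = None
) -> set[str]:
    """Genes disease-specifically DE at any time point.

    Selection by the overall moderated F across the double-difference
    contrasts at BH-adjusted p < alpha_overall_hd.
    """
    thresholds = thresholds or DEThresholds()
    ov = result.overall
    return set(ov.loc[ov["adj_p"] < thresholds.alpha_overall_hd, "gene_id"])


def select_early_response(
    result: ContrastResult, thresholds: DEThresholds | None = None
) -> set[str]:
    """Genes with a persistent early disease-specific response.

    Nominal double-difference p < alpha_early at every early time point
    (4, 8 and 24 h by default).
    """
    thresholds = thresholds or DEThresholds()
    dd = result.per_timepoint["DD"]
    sets = []
    for t_h in thresholds.early_timepoints:
        sub = dd[dd["time_h"] == float(t_h)]
        sets.append(set(sub.loc[sub["p"] < thresholds.alpha_early, "gene_id"]))
    if not sets:
        return set()
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def _condition_profiles(
    expr: pd.DataFrame, meta: pd.DataFrame, cellline: str = "HD"
) -> pd.DataFrame:
    """Average replicate arrays per time point within one cell line."""
    cols = meta.index[meta["cellline"] == cellline]
    sub = expr[cols]
    times = meta.loc[cols, "time_h"]
    prof = sub.T.groupby(times.values).mean().T
    return prof[sorted(prof.columns)]


def cluster_profiles(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    genes: set[str] | list[str],
    n_clusters: int = 2,
    cellline: str = "HD",
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster standardized temporal profiles of a gene set.

    Replicates of the same condition are averaged, each gene's profile is
    standardized to mean 0 / sd 1, and average-linkage hierarchical
    clustering with Pearson-correlation distance is cut at ``n_clusters``.
    Returns (labels per gene, tidy cluster mean +- sd profiles).  Cluster
    ids are canonicalized by decreasing cluster size so labelling does not
    depend on gene input order.
    """
    genes = sorted(set(genes) & set(expr.index))
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to cluster")
    prof = _condition_profiles(expr.loc[genes], meta, cellline=cellline)
    z = prof.to_numpy()
    sd = z.std(axis=1, ddof=0)
    if np.any(sd == 0):
        flat = prof.index[sd == 0].tolist()
        raise ValueError(f"constant profiles cannot be standardized: {flat[:5]}")
    z = (z - z.mean(axis=1, keepdims=True)) / sd[:, None]

    dist = pdist(z, metric="correlation")
    link = hierarchy.linkage(dist, method="average")
    raw = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")

    # canonical labels: by decreasing size, ties by smallest member gene id
    order = sorted(
        set(raw),
        key=lambda c: (-(raw == c).sum(), min(g for g, r in zip(genes, raw) if r == c)),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[r] for r in raw], index=genes, name="cluster")

    zdf = pd.DataFrame(z, index=genes, columns=prof.columns)
    rows = []
    for c in sorted(labels.unique()):
        members = zdf.loc[labels[labels == c].index]
        for t_h in zdf.columns:
            rows.append(
                {
                    "cluster": c,
                    "time_h": float(t_h),
                    "mean": float(members[t_h].mean()),
                    "sd": float(members[t_h].std(ddof=0)),
                    "n_genes": len(members),
                }
            )
    return labels, pd.DataFrame(rows)


# ---------------------------------------------------------------- figures


def _agg_pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_de_counts(counts: pd.DataFrame, path=None):
    """Up/down DE gene counts over time, one line pair per contrast family."""
    plt = _agg_pyplot()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = {"C": "tab:blue", "HD": "tab:red", "DD": "tab:orange"}
    for fam, sub in counts.groupby("family"):
        sub = sub.sort_values("time_h")
        ax.plot(sub["time_h"], sub["n_up"], marker="o", color=colors.get(fam), label=f"{fam} up")
        ax.plot(sub["time_h"], -sub["n_down"], marker="s", linestyle="--",
                color=colors.get(fam), label=f"{fam} down")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("time post-induction (h)")
    ax.set_ylabel("DE genes (up / -down)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_pca(scores: pd.DataFrame, explained, path=None):
    """PC1/PC2 scatter coloured by time, marker by cell line."""
    plt = _agg_pyplot()
    fig, ax = plt.subplots(figsize=(5.5, 5))
    markers = {"C": "o", "HD": "^"}
    times = sorted(scores["time_h"].unique())
    cmap = plt.get_cmap("viridis", len(times))
    for (line, t_h), sub in scores.groupby(["cellline", "time_h"]):
        ax.scatter(
            sub["PC1"], sub["PC2"],
            marker=markers.get(line, "o"),
            color=cmap(times.index(t_h)),
            label=f"{line} {t_h:g}h", s=30,
        )
    ax.set_xlabel(f"PC1 ({100 * explained[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * explained[1]:.1f}%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_cluster_profiles(cluster_summary: pd.DataFrame, path=None):
    """Standardized mean +- sd profile per cluster."""
    plt = _agg_pyplot()
    clusters = sorted(cluster_summary["cluster"].unique())
    fig, axes = plt.subplots(
        1, len(clusters), figsize=(4 * len(clusters), 3.5), squeeze=False
    )
    for ax, c in zip(axes[0], clusters):
        sub = cluster_summary[cluster_summary["cluster"] == c].sort_values("time_h")
        ax.errorbar(sub["time_h"], sub["mean"], yerr=sub["sd"], marker="o", capsize=3)
        ax.set_title(f"cluster {c} (n={int(sub['n_genes'].iloc[0])})")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("standardized expression")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
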