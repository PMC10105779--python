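"""Metabolite and lipid analytics.

The pathway differential-abundance (DA) score summarizes how a KEGG-style
metabolic pathway shifts between two patient groups: each profiled metabolite
is tested with a two-sided Mann-Whitney U test, called increased/decreased at
the chosen alpha by the sign of the median difference, and the pathway scores

    DA = (n_increased - n_decreased) / n_measured  in [-1, 1]

A score of 1 means every profiled metabolite of the pathway is up in the
positive group; -1 means all are down. Pathways with fewer than three profiled
metabolites are excluded.

Metabolite subtyping uses similarity network fusion (SNF): per-layer sample
affinity networks (scaled exponential kernel) are fused by iterative
cross-diffusion through each layer's k-nearest-neighbour kernel, and the fused
network is cut by spectral clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu
from sklearn.cluster import SpectralClustering
from statsmodels.stats.multitest import multipletests

from .expression import SubtypeAssignment


# ---------------------------------------------------------------------------
# tumor-vs-normal prefilter
# ---------------------------------------------------------------------------

def prefilter_features(
    tumor: pd.DataFrame,
    normal: pd.DataFrame | None,
    fdr_cut: float = 0.01,
    lfc_cut: float = 1.0,
    top_sd: int = 200,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Keep features with significant tumor-normal differences, then truncate
    to the most variable.

    Per feature: two-sided Mann-Whitney U between tumor and normal columns,
    Benjamini-Hochberg FDR across features; a feature survives when
    FDR < ``fdr_cut`` AND |log2 fold change| > ``lfc_cut`` (both strict).
    Survivors are ranked by SD across tumor samples and the top ``top_sd``
    retained (200 for polar metabolites, 400 for lipids in the reference
    design). With no normal matrix the difference filter is skipped with a
    warning and only the SD truncation applies. ``log_scale=True`` treats the
    matrices as log2 abundances (fold change = difference of means).
    """
    if normal is None or normal.shape[1] == 0:
        warnings.warn("no normal columns: skipping tumor-normal prefilter", stacklevel=2)
        surviving = tumor
    else:
        common = tumor.index.intersection(normal.index)
        t, n = tumor.loc[common], normal.loc[common]
        pvals = np.array(
            [
                mannwhitneyu(t.loc[f], n.loc[f], alternative="two-sided").pvalue
                for f in common
            ]
        )
        fdr = multipletests(pvals, method="fdr_bh")[1]
        if log_scale:
            lfc = (t.mean(axis=1) - n.mean(axis=1)).to_numpy()
        else:
            lfc = np.log2(t.mean(axis=1).to_numpy() / n.mean(axis=1).to_numpy())
        keep = (fdr < fdr_cut) & (np.abs(lfc) > lfc_cut)
        surviving = tumor.loc[common[keep]]
    sds = surviving.std(axis=1, ddof=1)
    top = sds.sort_values(ascending=False, kind="mergesort").index[:top_sd]
    return surviving.loc[top]


# ---------------------------------------------------------------------------
# DA score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DaResult:
    pathway: str
    n_measured: int
    n_increased: int
    n_decreased: int
    p_values: pd.Series = field(repr=False)

    @property
    def da_score(self) -> float:
        return (self.n_increased - self.n_decreased) / self.n_measured


def da_score(
    matrix: pd.DataFrame,
    groups: pd.Series,
    annotation: pd.DataFrame,
    positive_group: str,
    reference_group: str,
    alpha: float = 0.05,
    min_pathway_size: int = 3,
) -> list[DaResult]:
    """Pathway DA scores between two patient groups.

    ``groups`` maps sample id -> group label; ``annotation`` is a tidy table
    with columns ``feature`` and ``pathway`` (a metabolite may map to several
    pathways). Each metabolite is tested once (two-sided Mann-Whitney U,
    positive vs. reference samples, raw P < ``alpha``), its direction is the
    sign of the median difference, and every pathway with at least
    ``min_pathway_size`` profiled metabolites gets a score.
    """
    pos = groups.index[groups == positive_group]
    ref = groups.index[groups == reference_group]
    pos = [s for s in pos if s in matrix.columns]
    ref = [s for s in ref if s in matrix.columns]
    if len(pos) < 2 or len(ref) < 2:
        raise ValueError("each group needs at least 2 samples present in the matrix")

    measured = annotation[annotation["feature"].isin(matrix.index)]
    features = measured["feature"].unique()
    calls: dict[str, int] = {}
    pvals: dict[str, float] = {}
    for f in features:
        a = matrix.loc[f, pos].to_numpy(dtype=float)
        b = matrix.loc[f, ref].to_numpy(dtype=float)
        p = mannwhitneyu(a, b, alternative="two-sided").pvalue
        pvals[f] = float(p)
        direction = np.sign(np.median(a) - np.median(b))
        calls[f] = int(direction) if p < alpha and direction != 0 else 0

    results = []
    for pathway, grp in measured.groupby("pathway"):
        members = grp["feature"].unique()
        if len(members) < min_pathway_size:
            continue
        inc = sum(calls[f] > 0 for f in members)
        dec = sum(calls[f] < 0 for f in members)
        results.append(
            DaResult(
                pathway=str(pathway),
                n_measured=len(members),
                n_increased=inc,
                n_decreased=dec,
                p_values=pd.Series({f: pvals[f] for f in members}),
            )
        )
    return results


def da_table(results: list[DaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "n_measured": r.n_measured,
                "n_increased": r.n_increased,
                "n_decreased": r.n_decreased,
                "da_score": r.da_score,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# lipid subclass fold changes
# ---------------------------------------------------------------------------

LIPID_CATEGORIES = ("FA", "GL", "GP", "SP", "ST")


def lipid_subclass_fc(
    matrix: pd.DataFrame,
    groups: pd.Series,
    annotation: pd.DataFrame,
    positive_group: str,
    reference_group: str,
    log_scale: bool = True,
    convention: str = "ratio_of_means",
) -> pd.DataFrame:
    """Per-lipid log2 fold changes aggregated per subclass.

    ``annotation`` needs columns ``feature``, ``category`` (FA/GL/GP/SP/ST)
    and ``main_class``. With ``log_scale=True`` the matrix holds log2
    abundances and the per-lipid fold change is the difference of group means
    ('ratio_of_means' on the linear scale); ``convention='mean_of_ratios'``
    averages per-lipid log2 ratios over positive samples against the reference
    mean. Returns one row per main class with median/IQR of member fold
    changes.
    """
    bad = ~annotation["category"].isin(LIPID_CATEGORIES)
    if bad.any():
        raise ValueError(
            f"unknown lipid categories: {sorted(annotation.loc[bad, 'category'].unique())}"
        )
    pos = [s for s in groups.index[groups == positive_group] if s in matrix.columns]
    ref = [s for s in groups.index[groups == reference_group] if s in matrix.columns]
    ann = annotation[annotation["feature"].isin(matrix.index)]
    rows = []
    for (category, main_class), grp in ann.groupby(["category", "main_class"]):
        members = grp["feature"].unique()
        if len(members) == 0:
            warnings.warn(f"lipid subclass {main_class!r} has no measured members", stacklevel=2)
            continue
        sub = matrix.loc[members]
        if not log_scale:
            sub = np.log2(sub)
        if convention == "ratio_of_means":
            fc = sub[pos].mean(axis=1) - sub[ref].mean(axis=1)
        elif convention == "mean_of_ratios":
            fc = (sub[pos].sub(sub[ref].mean(axis=1), axis=0)).mean(axis=1)
        else:
            raise ValueError(f"unknown fold-change convention {convention!r}")
        q1, med, q3 = np.percentile(fc, [25, 50, 75])
        rows.append(
            {
                "category": category,
                "main_class": main_class,
                "n_lipids": len(members),
                "median_log2fc": med,
                "iqr_low": q1,
                "iqr_high": q3,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# similarity network fusion
# ---------------------------------------------------------------------------

def _affinity(x: np.ndarray, k: int, alpha: float) -> np.ndarray:
    """Scaled exponential-kernel affinity from Euclidean distances.

    The kernel bandwidth at (i, j) is alpha times the mean of the two points'
    mean distances to their k nearest neighbours and their own distance."""
    d = cdist(x, x)
    n = d.shape[0]
    k_eff = min(k, n - 1)
    sorted_d = np.sort(d, axis=1)
    mean_knn = sorted_d[:, 1 : k_eff + 1].mean(axis=1)  # exclude self
    sigma = alpha * (mean_knn[:, None] + mean_knn[None, :] + d) / 3.0
    sigma = np.maximum(sigma, np.finfo(float).eps)
    w = np.exp(-(d**2) / (2 * sigma**2))
    return (w + w.T) / 2


def _row_normalize(w: np.ndarray) -> np.ndarray:
    """SNF transition matrix: half the mass on the diagonal, half spread over
    the off-diagonal affinities."""
    n = w.shape[0]
    p = np.zeros_like(w)
    off = w - np.diag(np.diag(w))
    row_sums = off.sum(axis=1)
    nz = row_sums > 0
    p[nz] = off[nz] / (2 * row_sums[nz, None])
    np.fill_diagonal(p, 0.5)
    return p


def _knn_kernel(w: np.ndarray, k: int) -> np.ndarray:
    n = w.shape[0]
    k_eff = min(k, n - 1)
    s = np.zeros_like(w)
    for i in range(n):
        order = np.argsort(w[i])[::-1]
        neighbors = [j for j in order if j != i][:k_eff]
        s[i, neighbors] = w[i, neighbors]
    row = s.sum(axis=1)
    row[row == 0] = 1
    return s / row[:, None]


def snf_fuse(
    layers: list[pd.DataFrame],
    k_neighbors: int = 20,
    alpha: float = 0.5,
    iterations: int = 20,
) -> pd.DataFrame:
    """Fuse two or more sample x feature layers into one similarity network.

    Each layer is standardized per feature, converted to a scaled exponential
    kernel affinity, and the full kernels are iteratively cross-diffused
    through the other layers' k-nearest-neighbour kernels (canonical SNF with
    K=20, alpha=0.5, T=20). The fused matrix is symmetric and non-negative,
    indexed by the shared sample ids.
    """
    if len(layers) < 2:
        raise ValueError("SNF needs at least two layers")
    samples = layers[0].index
    for layer in layers[1:]:
        if not layer.index.equals(samples):
            raise ValueError("all layers must share an identical sample index")
    ps, ss = [], []
    for layer in layers:
        x = layer.to_numpy(dtype=float)
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
        w = _affinity(x, k_neighbors, alpha)
        ps.append(_row_normalize(w))
        ss.append(_knn_kernel(w, k_neighbors))
    m = len(layers)
    for _ in range(iterations):
        new_ps = []
        for v in range(m):
            others = sum(ps[u] for u in range(m) if u != v) / (m - 1)
            p = ss[v] @ others @ ss[v].T
            new_ps.append(_row_normalize((p + p.T) / 2))
        ps = new_ps
    fused = sum(ps) / m
    fused = (fused + fused.T) / 2
    return pd.DataFrame(fused, index=samples, columns=samples)


def snf_cluster(fused: pd.DataFrame, k: int = 3, seed: int = 0) -> list[SubtypeAssignment]:
    """Cut a fused similarity network into k subtypes by spectral clustering."""
    n = fused.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    if k == 1:
        return [
            SubtypeAssignment(sample=str(s), subtype=0, kind="metabolite", silhouette=0.0)
            for s in fused.index
        ]
    sc = SpectralClustering(n_clusters=k, affinity="precomputed", random_state=seed, assign_labels="kmeans")
    labels = sc.fit_predict(fused.to_numpy())
    # silhouette on the dissimilarity implied by the fused affinity
    d = 1.0 - fused.to_numpy() / fused.to_numpy().max()
    np.fill_diagonal(d, 0.0)
    from sklearn.metrics import silhouette_samples

    sil = silhouette_samples(d, labels, metric="precomputed") if len(np.unique(labels)) > 1 else np.zeros(n)
    return [
        SubtypeAssignment(sample=str(s), subtype=int(l), kind="metabolite", silhouette=float(v))
        for s, l, v in zip(fused.index, labels, sil)
    ]
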