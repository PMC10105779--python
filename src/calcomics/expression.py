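"""Expression-based scoring and subtyping.

Three flavours of per-sample summaries over a log-scale genes x samples
matrix:

* the 3-step signature score (mean-center each gene across samples, average
  over the signature's genes, z-score across the cohort) used for
  literature-defined immune signatures, immunotherapy-response signatures and
  metabolic signatures;
* single-sample GSEA (ssGSEA): a rank-weighted Kolmogorov-Smirnov running sum
  per gene set per sample, used to infer tumor-microenvironment (TME) cell
  infiltration from cell-type marker sets;
* k-means subtype assignment (mRNA subtype on the top-variance genes, immune
  subtype on scaled cell-infiltration scores).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples, silhouette_score
from sklearn.preprocessing import StandardScaler


def signature_score(matrix: pd.DataFrame, genes: list[str], name: str = "signature") -> pd.Series:
    """Per-sample signature score: (1) mean-center each gene across all
    samples; (2) average over the signature genes; (3) z-score across samples.

    Signature genes absent from the matrix are dropped with a warning; no
    overlap at all is an error. The output has cohort mean 0 and SD 1.
    """
    if matrix.shape[1] < 2:
        raise ValueError("signature_score needs at least 2 samples")
    present = [g for g in genes if g in matrix.index]
    missing = sorted(set(genes) - set(present))
    if not present:
        raise ValueError(f"signature {name!r}: no genes overlap the matrix")
    if missing:
        warnings.warn(f"signature {name!r}: {len(missing)} gene(s) not in matrix", stacklevel=2)
    sub = matrix.loc[present]
    centered = sub.sub(sub.mean(axis=1), axis=0)
    avg = centered.mean(axis=0)
    return ((avg - avg.mean()) / avg.std(ddof=1)).rename(name)


def score_signatures(matrix: pd.DataFrame, signatures: dict[str, list[str]]) -> pd.DataFrame:
    """Signature x sample score table for a collection of gene sets."""
    return pd.DataFrame({n: signature_score(matrix, g, name=n) for n, g in signatures.items()}).T


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def _ssgsea_sample(values: np.ndarray, in_set: np.ndarray, weight_exponent: float) -> float:
    """ssGSEA enrichment of one gene set in one sample.

    Genes are ordered by decreasing expression rank (ties by average rank);
    in-set steps are weighted by rank^exponent, out-of-set steps are uniform,
    and the score is the sum of the running difference.
    """
    n = len(values)
    ranks = rankdata(values)  # 1 = lowest expression
    order = np.argsort(-ranks, kind="stable")  # highest expression first
    in_ordered = in_set[order]
    w = np.abs(ranks[order]) ** weight_exponent
    w_in = np.where(in_ordered, w, 0.0)
    denom_in = w_in.sum()
    n_out = n - int(in_set.sum())
    p_in = np.cumsum(w_in) / denom_in
    if n_out == 0:
        p_out = np.zeros(n)
    else:
        p_out = np.cumsum(~in_ordered) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    matrix: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    weight_exponent: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Set x sample ssGSEA score matrix.

    With ``normalize=True`` scores are min-max scaled by the absolute range of
    the whole score matrix (cross-cohort normalization). A gene set with no
    members in the matrix is an error naming the set.
    """
    features = matrix.index
    masks = {}
    for name, genes in gene_sets.items():
        mask = np.asarray(features.isin(genes))
        if not mask.any():
            raise ValueError(f"gene set {name!r} has no members in the matrix")
        masks[name] = mask
    x = matrix.to_numpy(dtype=float)
    out = np.empty((len(masks), matrix.shape[1]))
    for i, mask in enumerate(masks.values()):
        for j in range(x.shape[1]):
            out[i, j] = _ssgsea_sample(x[:, j], mask, weight_exponent)
    scores = pd.DataFrame(out, index=list(masks), columns=matrix.columns)
    if normalize:
        rng = scores.to_numpy().max() - scores.to_numpy().min()
        if rng > 0:
            scores = scores / rng
    return scores


def infer_tme(matrix: pd.DataFrame, cell_reference: dict[str, list[str]], **kwargs) -> pd.DataFrame:
    """Cell-type x sample infiltration scores: ssGSEA over a compendium of
    TME cell-type marker gene sets (24 cell types in the reference design)."""
    return ssgsea_scores(matrix, cell_reference, **kwargs)


# ---------------------------------------------------------------------------
# subtype clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubtypeAssignment:
    sample: str
    subtype: int
    kind: str
    silhouette: float


def _assignments(labels: np.ndarray, x: np.ndarray, samples, kind: str) -> list[SubtypeAssignment]:
    if len(np.unique(labels)) > 1:
        sil = silhouette_samples(x, labels)
    else:
        sil = np.zeros(len(labels))
    return [
        SubtypeAssignment(sample=str(s), subtype=int(l), kind=kind, silhouette=float(v))
        for s, l, v in zip(samples, labels, sil)
    ]


def cluster_mrna_subtype(
    matrix: pd.DataFrame, n_top_sd: int = 2000, k: int = 4, seed: int = 0, n_init: int = 10
) -> list[SubtypeAssignment]:
    """mRNA subtype by k-means on the top-SD genes (samples as points).

    Genes are ranked by standard deviation across samples and the top
    ``n_top_sd`` retained (all, if fewer); k defaults to the four-subtype
    TNBC scheme. Marker-based naming of the clusters is the caller's concern.
    """
    if matrix.shape[1] < k:
        raise ValueError(f"need at least k={k} samples, got {matrix.shape[1]}")
    sds = matrix.std(axis=1, ddof=1)
    top = sds.sort_values(ascending=False, kind="mergesort").index[:n_top_sd]
    x = matrix.loc[top].T.to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(x)
    return _assignments(labels, x, matrix.columns, "mrna")


def cluster_immune_subtype(
    cell_scores: pd.DataFrame, k: int, seed: int = 0, n_init: int = 10
) -> list[SubtypeAssignment]:
    """Immune subtype by k-means on per-cell-type scaled infiltration scores
    (cell types standardized across samples). k is caller-specified; see
    :func:`silhouette_scan` for choosing it."""
    if cell_scores.shape[1] < k:
        raise ValueError(f"need at least k={k} samples, got {cell_scores.shape[1]}")
    x = cell_scores.T.to_numpy(dtype=float)
    sds = x.std(axis=0)
    if (sds == 0).all():
        warnings.warn("constant score matrix: immune clustering is degenerate", stacklevel=2)
    x = StandardScaler().fit_transform(x)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(x)
    return _assignments(labels, x, cell_scores.columns, "immune")


def silhouette_scan(
    matrix: pd.DataFrame, k_range=range(2, 9), seed: int = 0, scale: bool = True
) -> pd.Series:
    """Mean silhouette width of k-means solutions over a range of k
    (samples = columns). A pragmatic replacement for multi-index cluster-number
    votes: pick the k maximizing the silhouette, or inspect the curve."""
    x = matrix.T.to_numpy(dtype=float)
    if scale:
        x = StandardScaler().fit_transform(x)
    out = {}
    for k in k_range:
        if k >= len(x):
            break
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(x)
        out[k] = silhouette_score(x, labels) if len(np.unique(labels)) > 1 else float("nan")
    return pd.Series(out, name="silhouette")
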