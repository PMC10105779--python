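"""Somatic-mutation analytics: burden, clustered mutations, SBS96 catalogs,
reference-signature refitting, and neoantigen filtering.

Tumor mutation burden (TMB) is the number of nonsynonymous somatic mutations
per megabase of captured coding exome; the default footprint of 35.618 Mb is
the capture size of the exome kit the scores were designed around.

Clustered mutations are detected from inter-mutational distances (IMD): a
per-sample IMD threshold is calibrated against a uniform-placement background
(100 simulated catalogs by default), and maximal runs of mutations closer than
the threshold are classified as doublet-base substitutions (DBS), multi-base
substitutions (MBS), diffuse hypermutation (omikli) or kataegis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .genome import GenomeBuild

DEFAULT_EXOME_FOOTPRINT_MB = 35.618

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical SBS96 class labels, pyrimidine strand: 6 substitutions x 16
#: trinucleotide contexts, e.g. "A[C>A]A".
SBS96_CLASSES = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)


# ---------------------------------------------------------------------------
# tumor mutation burden
# ---------------------------------------------------------------------------

def compute_tmb(
    mutations: pd.DataFrame, footprint_mb: float = DEFAULT_EXOME_FOOTPRINT_MB
) -> pd.Series:
    """Nonsynonymous mutations per megabase, per sample.

    Silent and non-coding classes are excluded; the denominator is the coding
    footprint of the capture kit in Mb.
    """
    if footprint_mb <= 0:
        raise ValueError("footprint_mb must be positive")
    if "is_nonsynonymous" not in mutations.columns:
        from .io import NONSYNONYMOUS_CLASSES

        mutations = mutations.assign(
            is_nonsynonymous=mutations["Variant_Classification"].isin(NONSYNONYMOUS_CLASSES)
        )
    counts = mutations.groupby("Tumor_Sample_Barcode")["is_nonsynonymous"].sum()
    return (counts / footprint_mb).rename("tmb")


# ---------------------------------------------------------------------------
# clustered mutations
# ---------------------------------------------------------------------------

def _snvs(mutations: pd.DataFrame) -> pd.DataFrame:
    ok = mutations["Reference_Allele"].isin(list(BASES)) & mutations["Tumor_Seq_Allele2"].isin(
        list(BASES)
    )
    return mutations[ok]


def _real_imds(snvs: pd.DataFrame) -> np.ndarray:
    imds = []
    for _, grp in snvs.groupby("Chromosome"):
        pos = np.sort(grp["Start_Position"].to_numpy())
        if len(pos) >= 2:
            imds.append(np.diff(pos))
    return np.concatenate(imds) if imds else np.array([], dtype=int)


@dataclass(frozen=True)
class ImdThreshold:
    """Result of the per-sample IMD calibration."""

    sample: str
    threshold: int | None
    n_simulations: int
    n_mutations: int
    q_value: float | None = None
    clustered_fraction: float | None = None


def imd_threshold(
    mutations: pd.DataFrame,
    build: GenomeBuild,
    n_simulations: int = 100,
    q_cut: float = 0.1,
    clustered_fraction: float = 0.9,
    seed: int | np.random.Generator = 0,
) -> ImdThreshold:
    """Calibrate a per-sample IMD threshold against a uniform background.

    The sample's somatic SNVs are re-placed uniformly within their chromosomes
    ``n_simulations`` times. A candidate threshold T qualifies when (a) the
    estimated fraction of real sub-T inter-mutational distances not explained
    by the background exceeds ``clustered_fraction`` and (b) the simulation
    q-value (fraction of simulations with at least as many sub-T distances as
    observed) is below ``q_cut``. The largest qualifying T is returned;
    ``threshold=None`` when no T qualifies or the sample has fewer than two
    SNVs on every chromosome.

    The background re-places positions uniformly per chromosome rather than
    preserving sequence context — a deliberate desk-scale simplification.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ids = mutations["Tumor_Sample_Barcode"].unique()
    if len(ids) != 1:
        raise ValueError("imd_threshold operates on one sample at a time")
    sample = ids[0]
    snvs = _snvs(mutations)
    real = _real_imds(snvs)
    n_mut = len(snvs)
    if real.size == 0:
        return ImdThreshold(sample, None, n_simulations, n_mut)

    per_chrom = snvs.groupby("Chromosome").size()
    sim_imds = []
    for _ in range(n_simulations):
        parts = []
        for chrom, m in per_chrom.items():
            if m < 2:
                continue
            pos = np.sort(rng.integers(1, build.length(chrom) + 1, size=m))
            parts.append(np.diff(pos))
        sim_imds.append(np.sort(np.concatenate(parts)) if parts else np.array([], dtype=int))

    real_sorted = np.sort(real)
    best = None
    for t in np.unique(real)[::-1]:
        r = int(np.searchsorted(real_sorted, t, side="right"))
        if r == 0:
            continue
        c = np.array([np.searchsorted(s, t, side="right") for s in sim_imds])
        q = (1 + int((c >= r).sum())) / (n_simulations + 1)
        frac = 1.0 - c.mean() / r
        if frac >= clustered_fraction and q < q_cut:
            best = ImdThreshold(sample, int(t), n_simulations, n_mut, q, float(frac))
            break  # scanning descending: first hit is the largest qualifying T
    if best is None:
        return ImdThreshold(sample, None, n_simulations, n_mut)
    return best


def classify_clustered_mutations(
    mutations: pd.DataFrame, threshold: int | None, kataegis_min_size: int = 4
) -> pd.DataFrame:
    """Partition one sample's SNVs into clustered-mutation classes.

    Maximal runs of same-chromosome mutations with consecutive IMD <= threshold
    form clusters; each cluster is classified:

    * DBS — exactly 2 mutations at adjacent positions (IMD 1);
    * MBS — >= 3 mutations, all at adjacent positions;
    * omikli — 2 or 3 mutations with at least one IMD > 1;
    * kataegis — >= ``kataegis_min_size`` mutations with at least one IMD > 1;

    everything else is non_clustered. Returns the input rows (SNVs only) with
    ``cluster_id`` (nullable int) and ``cluster_class`` columns; input order
    does not matter.
    """
    snvs = _snvs(mutations).sort_values(["Chromosome", "Start_Position"]).copy()
    snvs["cluster_id"] = pd.array([pd.NA] * len(snvs), dtype="Int64")
    snvs["cluster_class"] = "non_clustered"
    if threshold is None or len(snvs) < 2:
        return snvs
    cluster_id = 0
    for _, grp in snvs.groupby("Chromosome"):
        pos = grp["Start_Position"].to_numpy()
        idx = grp.index.to_numpy()
        run = [0]
        for i in range(1, len(pos)):
            if pos[i] - pos[i - 1] <= threshold:
                run.append(i)
            else:
                cluster_id = _emit_cluster(snvs, idx, pos, run, cluster_id, kataegis_min_size)
                run = [i]
        cluster_id = _emit_cluster(snvs, idx, pos, run, cluster_id, kataegis_min_size)
    return snvs


def _emit_cluster(snvs, idx, pos, run, cluster_id, kataegis_min_size) -> int:
    if len(run) < 2:
        return cluster_id
    members = idx[run]
    imds = np.diff(pos[run])
    size = len(run)
    if size == 2 and (imds == 1).all():
        label = "DBS"
    elif size >= 3 and (imds == 1).all():
        label = "MBS"
    elif size >= kataegis_min_size:
        label = "kataegis"
    elif size <= 3:
        label = "omikli"
    else:  # size between 4-exclusive bounds can't occur with default, guard anyway
        label = "omikli"
    snvs.loc[members, "cluster_id"] = cluster_id
    snvs.loc[members, "cluster_class"] = label
    return cluster_id + 1


# ---------------------------------------------------------------------------
# SBS96 catalogs
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def sbs96_class(ref: str, alt: str, context: str) -> str:
    """Canonical SBS96 class of one SNV: purine-reference mutations are
    collapsed onto the pyrimidine strand by reverse complement."""
    if len(context) != 3:
        raise ValueError(f"trinucleotide context must have length 3, got {context!r}")
    if context[1] != ref:
        raise ValueError(f"context {context!r} center does not match ref {ref!r}")
    if ref in "AG":
        context = _revcomp(context)
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def build_sbs96(mutations: pd.DataFrame, context_column: str = "Trinucleotide_Context") -> pd.Series:
    """SBS96 count vector for one sample's SNVs (non-SNVs ignored).

    The result is indexed by :data:`SBS96_CLASSES` and sums to the number of
    contributing SNVs.
    """
    snvs = _snvs(mutations)
    counts = pd.Series(0, index=list(SBS96_CLASSES), dtype=int)
    for ref, alt, ctx in snvs[["Reference_Allele", "Tumor_Seq_Allele2", context_column]].itertuples(
        index=False
    ):
        counts[sbs96_class(ref, alt, ctx)] += 1
    return counts


def sbs96_matrix(mutations: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """96 x samples catalog matrix for a multi-sample mutation table."""
    cols = {
        sample: build_sbs96(grp, **kwargs)
        for sample, grp in mutations.groupby("Tumor_Sample_Barcode")
    }
    return pd.DataFrame(cols).reindex(list(SBS96_CLASSES)).fillna(0).astype(int)


# ---------------------------------------------------------------------------
# signature refitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureExposure:
    sample: str
    exposures: pd.Series = field(repr=False)
    reconstruction_error: float
    cosine_similarity: float


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def refit_signatures(
    catalog: pd.Series,
    reference: pd.DataFrame,
    sparsity_tol: float | None = 0.01,
    sample: str | None = None,
) -> SignatureExposure:
    """Decompose one SBS96 catalog into non-negative exposures to reference
    signatures by non-negative least squares.

    ``reference`` is a signatures x 96 matrix with rows summing to 1. With
    ``sparsity_tol`` set, a backward-elimination pass repeatedly drops the
    lowest-exposure signature as long as the cosine similarity between the
    catalog and its reconstruction worsens by less than the tolerance relative
    to the dense fit; ``sparsity_tol=None`` disables the pass.
    """
    ref = reference.reindex(columns=catalog.index)
    if ref.isna().any().any():
        raise ValueError("reference signature matrix does not cover the catalog's 96 classes")
    b = catalog.to_numpy(dtype=float)
    names = list(ref.index)

    def fit(active: list[str]):
        a = ref.loc[active].to_numpy(dtype=float).T  # 96 x k
        w, rnorm = nnls(a, b)
        recon = a @ w
        return pd.Series(w, index=active), rnorm, _cosine(b, recon)

    exposures, rnorm, cos_full = fit(names)
    if sparsity_tol is not None:
        active = list(exposures.index)
        while len(active) > 1:
            candidate = exposures.loc[active].idxmin()
            trial = [s for s in active if s != candidate]
            w_trial, r_trial, cos_trial = fit(trial)
            if cos_full - cos_trial < sparsity_tol:
                active = trial
                exposures, rnorm = w_trial, r_trial
            else:
                break
        exposures = exposures.reindex(names).fillna(0.0)
        cos = fit([s for s in names if exposures[s] > 0] or names)[2]
    else:
        cos = cos_full
    return SignatureExposure(
        sample=sample or str(catalog.name or "sample"),
        exposures=exposures.reindex(names).fillna(0.0),
        reconstruction_error=float(rnorm),
        cosine_similarity=float(cos),
    )


# ---------------------------------------------------------------------------
# neoantigen filtering
# ---------------------------------------------------------------------------

def filter_neoantigens(
    candidates: pd.DataFrame, affinity_cut_nm: float = 500.0, expr_cut: float = 1.0
) -> pd.DataFrame:
    """Apply the neoantigen definition to precomputed peptide candidates.

    A candidate passes when predicted binding affinity is strictly below
    ``affinity_cut_nm`` (nM) AND the source gene's expression is strictly
    above ``expr_cut`` (batch-corrected units). Candidates with a missing
    affinity are skipped with a warning.
    """
    missing = candidates["affinity_nm"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} candidate(s) skipped: missing predicted affinity",
            stacklevel=2,
        )
    usable = candidates[~missing]
    keep = (usable["affinity_nm"] < affinity_cut_nm) & (usable["expression"] > expr_cut)
    return usable[keep].copy()
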