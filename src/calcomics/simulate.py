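"""Synthetic multi-omics cohort generator with planted group effects.

The generator emulates a mammographic TNBC cohort in which every downstream
statistic of the pipeline has a known ground truth: per-group somatic-mutation
frequencies (an elevated *PIK3CA* rate in the high-suspicion group),
allele-specific copy-number profiles with planted telomeric-imbalance, LOH and
state-transition scars plus HLA-I LOH, log-scale expression with a planted
immune-compendium shift, metabolite/lipid tables with planted tumor-normal
differences and a lipid-pathway shift, and exponential survival times with
per-group hazard ratios.

Planted scar events are allocated to disjoint chromosome-arm slots so the
constructed counts are exact: a telomeric allelic-imbalance event occupies a
telomere and leaves its residual arm shorter than the LST flank threshold; an
LOH run sits mid-arm with both flanks short; an LST event is a mid-arm
copy-state block whose two boundaries both have long flanks (2 breakpoints).
All randomness flows from the single spec seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .genome import MB, GenomeBuild, synthetic_build

GROUPS = cio.CALCIFICATION_GROUPS

DEFAULT_PROPORTIONS = {
    "negative": 0.55,
    "probably_benign": 0.11,
    "low_moderate": 0.08,
    "high_suspicion": 0.26,
}

DEFAULT_PIK3CA_FREQ = {
    "negative": 0.156,
    "probably_benign": 0.163,
    "low_moderate": 0.16,
    "high_suspicion": 0.296,
}

DEFAULT_SCAR_INTENSITY = {g: {"ntai": 3.0, "loh": 2.0, "lst": 4.0} for g in GROUPS}

_SUBSTITUTION_PROBS = {  # breast-like spectrum on the pyrimidine strand
    "C>T": 0.36,
    "C>A": 0.10,
    "C>G": 0.12,
    "T>C": 0.22,
    "T>A": 0.10,
    "T>G": 0.10,
}

_CLASS_PROBS = {
    "Missense_Mutation": 0.70,
    "Nonsense_Mutation": 0.10,
    "Splice_Site": 0.05,
    "Frame_Shift_Del": 0.04,
    "Frame_Shift_Ins": 0.04,
    "In_Frame_Del": 0.02,
    "In_Frame_Ins": 0.02,
    "Nonstop_Mutation": 0.01,
    "Translation_Start_Site": 0.02,
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Lipid main classes reported as shifted in the high-suspicion group.
SHIFTED_LIPID_CLASSES = ("triradylglycerols", "ceramides", "fatty_esters")

LIPID_PATHWAYS = (
    "Fatty acid metabolism",
    "Sphingolipid metabolism",
    "Glycerolipid metabolism",
    "Glycerophospholipid metabolism",
    "Steroid biosynthesis",
)

OTHER_PATHWAYS = (
    "Citrate cycle (TCA cycle)",
    "Glycolysis / Gluconeogenesis",
    "Pentose phosphate pathway",
    "Purine metabolism",
    "Pyrimidine metabolism",
    "Alanine, aspartate and glutamate metabolism",
    "Arginine biosynthesis",
    "Tryptophan metabolism",
    "Tyrosine metabolism",
    "Valine, leucine and isoleucine degradation",
    "Glutathione metabolism",
    "Nicotinate and nicotinamide metabolism",
    "Pantothenate and CoA biosynthesis",
    "Starch and sucrose metabolism",
    "Taurine and hypotaurine metabolism",
)

_LIPID_CLASSES = {
    "FA": ("fatty_acids", "fatty_esters"),
    "GL": ("triradylglycerols", "diradylglycerols"),
    "GP": ("glycerophosphocholines", "glycerophosphoethanolamines"),
    "SP": ("ceramides", "neutral_glycosphingolipids"),
    "ST": ("sterols", "steryl_esters"),
}


def _per_group(value, name: str) -> dict:
    """Broadcast a scalar to all groups; validate a per-group mapping."""
    if isinstance(value, dict):
        missing = set(GROUPS) - set(value)
        if missing:
            raise ValueError(f"{name} missing group(s): {sorted(missing)}")
        return {g: value[g] for g in GROUPS}
    return {g: value for g in GROUPS}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults are the study conditions."""

    n_samples: int = 312
    group_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    seed: int = 0
    mutation_rate: dict | float = 53.0
    pik3ca_freq: dict | float = field(default_factory=lambda: dict(DEFAULT_PIK3CA_FREQ))
    scar_intensity: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_SCAR_INTENSITY.items()})
    hla_loh_freq: dict | float = 0.2
    immune_shift: dict | float = field(
        default_factory=lambda: {"negative": 0.0, "probably_benign": 0.0, "low_moderate": 0.0, "high_suspicion": -1.0}
    )
    lipid_shift: dict | float = field(
        default_factory=lambda: {"negative": 0.0, "probably_benign": 0.0, "low_moderate": 0.0, "high_suspicion": 1.5}
    )
    hazard_ratio: dict | float = field(
        default_factory=lambda: {"negative": 1.0, "probably_benign": 1.0, "low_moderate": 1.0, "high_suspicion": 2.0}
    )
    censor_rate: float = 0.3
    baseline_hazard: float = 0.004  # events per month; median OS ~ 173 months
    n_filler_genes: int = 1000
    n_immune_genes: int = 50

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        total = sum(self.group_proportions.get(g, 0.0) for g in GROUPS)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group_proportions must sum to 1 (got {total})")
        unknown = set(self.group_proportions) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group(s) in proportions: {sorted(unknown)}")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ValueError("censor_rate must lie in [0, 1]")
        self.mutation_rate = _per_group(self.mutation_rate, "mutation_rate")
        self.pik3ca_freq = _per_group(self.pik3ca_freq, "pik3ca_freq")
        self.hla_loh_freq = _per_group(self.hla_loh_freq, "hla_loh_freq")
        self.immune_shift = _per_group(self.immune_shift, "immune_shift")
        self.lipid_shift = _per_group(self.lipid_shift, "lipid_shift")
        self.hazard_ratio = _per_group(self.hazard_ratio, "hazard_ratio")
        self.scar_intensity = _per_group(self.scar_intensity, "scar_intensity")
        for g, probs in self.pik3ca_freq.items():
            if not (0.0 <= probs <= 1.0):
                raise ValueError(f"pik3ca_freq[{g}] outside [0, 1]")
        for g, probs in self.hla_loh_freq.items():
            if not (0.0 <= probs <= 1.0):
                raise ValueError(f"hla_loh_freq[{g}] outside [0, 1]")


@dataclass
class SyntheticCohort:
    cohort: pd.DataFrame
    mutations: pd.DataFrame
    segments: pd.DataFrame
    expression: pd.DataFrame
    metabolites: pd.DataFrame
    metabolites_normal: pd.DataFrame
    lipids: pd.DataFrame
    lipids_normal: pd.DataFrame
    metabolite_annotation: pd.DataFrame
    lipid_annotation: pd.DataFrame
    signatures: dict
    tme_reference: dict
    hla_genotypes: dict
    build: GenomeBuild
    truth: dict

    def write(self, outdir) -> None:
        """Write every layer to standard text formats plus a truth JSON."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cio.write_cohort(self.cohort, out / "cohort.tsv")
        cio.write_maf(self.mutations, out / "mutations.maf.tsv")
        cio.write_segments(self.segments, out / "segments.seg.tsv")
        cio.write_matrix(self.expression, out / "expression.tsv", index_label="gene")
        cio.write_matrix(self.metabolites, out / "metabolites_tumor.tsv", index_label="metabolite")
        cio.write_matrix(self.metabolites_normal, out / "metabolites_normal.tsv", index_label="metabolite")
        cio.write_matrix(self.lipids, out / "lipids_tumor.tsv", index_label="lipid")
        cio.write_matrix(self.lipids_normal, out / "lipids_normal.tsv", index_label="lipid")
        self.metabolite_annotation.to_csv(out / "metabolite_annotation.tsv", sep="\t", index=False)
        self.lipid_annotation.to_csv(out / "lipid_annotation.tsv", sep="\t", index=False)
        cio.write_gmt(self.signatures, out / "signatures.gmt")
        cio.write_gmt(self.tme_reference, out / "tme_reference.synthetic.gmt")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# layer generators
# ---------------------------------------------------------------------------

_GENE_POOL = [f"GENE{i:04d}" for i in range(1, 61)] + ["TP53", "PTEN", "RB1", "NOTCH2", "FBXW7"]

_TME_CELL_TYPES = [
    "CD8_T_cells", "CD4_T_cells", "NK_cells", "B_cells", "Tregs", "Dendritic_cells",
    "Macrophages_M1", "Macrophages_M2", "Monocytes", "Neutrophils", "Eosinophils",
    "Mast_cells", "Plasma_cells", "Memory_B_cells", "Naive_CD4_T", "Memory_CD4_T",
    "Naive_CD8_T", "Gamma_delta_T", "NKT_cells", "Th1_cells", "Th2_cells", "Th17_cells",
    "Fibroblasts", "Endothelial_cells",
]


def _draw_groups(rng, spec: CohortSpec) -> list[str]:
    probs = [spec.group_proportions.get(g, 0.0) for g in GROUPS]
    counts = rng.multinomial(spec.n_samples, probs)
    labels = [g for g, c in zip(GROUPS, counts) for _ in range(c)]
    rng.shuffle(labels)
    return labels


def _simulate_mutations(rng, samples, groups, spec: CohortSpec, build: GenomeBuild) -> tuple[pd.DataFrame, dict]:
    chroms = build.names
    lengths = np.array([build.length(c) for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    subs = list(_SUBSTITUTION_PROBS)
    sub_p = np.array(list(_SUBSTITUTION_PROBS.values()))
    classes = list(_CLASS_PROBS)
    class_p = np.array(list(_CLASS_PROBS.values()))
    bases = list("ACGT")

    rows = []
    pik3ca_truth = {}
    for sample, group in zip(samples, groups):
        n_nonsyn = rng.poisson(spec.mutation_rate[group])
        has_pik3ca = bool(rng.random() < spec.pik3ca_freq[group])
        pik3ca_truth[sample] = has_pik3ca
        n_silent = rng.poisson(0.3 * spec.mutation_rate[group])
        specs = [("nonsyn", n_nonsyn), ("silent", n_silent)]
        for kind, n in specs:
            for _ in range(n):
                chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
                pos = int(rng.integers(1, build.length(chrom) + 1))
                sub = subs[rng.choice(len(subs), p=sub_p)]
                ref, alt = sub.split(">")
                if rng.random() < 0.5:  # place on the purine strand half the time
                    ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
                ctx = bases[rng.integers(4)] + ref + bases[rng.integers(4)]
                vclass = "Silent" if kind == "silent" else classes[rng.choice(len(classes), p=class_p)]
                gene = _GENE_POOL[rng.integers(len(_GENE_POOL))]
                rows.append((sample, gene, chrom, pos, ref, alt, vclass, ctx))
        if has_pik3ca:
            chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
            pos = int(rng.integers(1, build.length(chrom) + 1))
            flank5, flank3 = bases[rng.integers(4)], bases[rng.integers(4)]
            rows.append((sample, "PIK3CA", chrom, pos, "C", "T", "Missense_Mutation", flank5 + "C" + flank3))
    df = pd.DataFrame(
        rows,
        columns=cio.MAF_COLUMNS + ["Trinucleotide_Context"],
    )
    return cio.validate_mutations(df, build=build), pik3ca_truth


def _simulate_segments(rng, samples, groups, spec: CohortSpec, build: GenomeBuild):
    """Allele-specific segments with exactly-planted scar events.

    Slot scheme per chromosome (chr6 reserved for the HLA event): a telomeric
    AI event may occupy the p and/or q telomere; a q arm not hosting a
    telomeric event may instead host one interstitial LOH run or one LST
    double-breakpoint block.
    """
    hla_chrom = "chr6" if "chr6" in build.names else None
    usable = [c for c in build.names if c != hla_chrom]
    seg_rows = []
    truth_rows = {}
    for sample, group in zip(samples, groups):
        intensity = spec.scar_intensity[group]
        n_ntai = int(rng.poisson(intensity["ntai"]))
        n_loh = int(rng.poisson(intensity["loh"]))
        n_lst_blocks = int(rng.poisson(intensity["lst"] / 2.0))
        has_hla_loh = bool(rng.random() < spec.hla_loh_freq[group])

        order = list(usable)
        rng.shuffle(order)
        p_free = {c: True for c in order}
        q_free = {c: True for c in order}

        # planted intervals: chrom -> list of (start, end, nMajor, nMinor)
        planted: dict[str, list[tuple[int, int, int, int]]] = {c: [] for c in build.names}

        placed_ntai = 0
        for c in order + order:  # first pass p telomeres, second pass q telomeres
            if placed_ntai >= n_ntai:
                break
            length = build.length(c)
            ai_len = int(rng.uniform(38.5, 45.0) * MB)
            if p_free[c]:
                planted[c].append((1, ai_len, 2, 1))
                p_free[c] = False
                placed_ntai += 1
            elif q_free[c]:
                planted[c].append((length - ai_len + 1, length, 2, 1))
                q_free[c] = False
                placed_ntai += 1

        placed_loh = 0
        for c in order:
            if placed_loh >= n_loh:
                break
            if not q_free[c]:
                continue
            # mid-q LOH run >15 Mb with both flanks <= 10 Mb inside the arm,
            # so the run never creates an LST breakpoint or touches a telomere
            arm_lo, arm_hi = build.arms(c)[-1]
            loh_len = int(rng.uniform(29.5, 30.0) * MB)
            left_flank = int(rng.uniform(9.0, 9.8) * MB)
            start = arm_lo + left_flank
            if start + loh_len - 1 > arm_hi - int(3.0 * MB):
                continue
            planted[c].append((start, start + loh_len - 1, 1, 0))
            q_free[c] = False
            placed_loh += 1

        placed_blocks = 0
        for c in order:
            if placed_blocks >= n_lst_blocks:
                break
            if not q_free[c]:
                continue
            length = build.length(c)
            arm_lo = build.arms(c)[-1][0] if build.centromeres else length // 2
            block_len = int(rng.uniform(15.0, 20.0) * MB)
            start = arm_lo + int(rng.uniform(12.0, 14.0) * MB)
            planted[c].append((start, start + block_len - 1, 2, 2))
            q_free[c] = False
            placed_blocks += 1

        if has_hla_loh and hla_chrom is not None:
            lo = min(s for (_c, s, _e) in build.hla_loci.values())
            planted[hla_chrom].append((lo - 500_000, lo - 500_000 + 3 * MB - 1, 1, 0))

        for c in build.names:
            length = build.length(c)
            events = sorted(planted[c])
            cursor = 1
            for s, e, a, b in events:
                if s > cursor:
                    seg_rows.append((sample, c, cursor, s - 1, 1, 1))
                seg_rows.append((sample, c, s, e, a, b))
                cursor = e + 1
            if cursor <= length:
                seg_rows.append((sample, c, cursor, length, 1, 1))

        truth_rows[sample] = {
            "ntai": placed_ntai,
            "loh": placed_loh,
            "lst": 2 * placed_blocks,
            "hrd": placed_ntai + placed_loh + 2 * placed_blocks,
            "hla_loh": has_hla_loh,
        }
    segments = pd.DataFrame(seg_rows, columns=cio.SEG_COLUMNS)
    return cio.validate_segments(segments, build=build), truth_rows


def _simulate_hla_genotypes(rng, samples) -> dict:
    pools = {locus: [f"{locus[-1]}*{i:02d}:01" for i in range(1, 11)] for locus in ("HLA-A", "HLA-B", "HLA-C")}
    out = {}
    for sample in samples:
        out[sample] = {
            locus: (pool[rng.integers(len(pool))], pool[rng.integers(len(pool))])
            for locus, pool in pools.items()
        }
    return out


def _simulate_expression(rng, samples, groups, spec: CohortSpec):
    immune_genes = [f"IMM{i:03d}" for i in range(1, spec.n_immune_genes + 1)]
    tme_reference = {}
    tme_genes = []
    # 364 marker genes over 24 cell types, mirroring the compendium's size
    sizes = [16] * 4 + [15] * 20
    gi = 0
    for cell, size in zip(_TME_CELL_TYPES, sizes):
        members = [f"TME{gi + j:03d}" for j in range(size)]
        gi += size
        tme_reference[cell] = members
        tme_genes.extend(members)
    filler = [f"GENEX{i:04d}" for i in range(1, spec.n_filler_genes + 1)]
    genes = immune_genes + tme_genes + filler
    x = rng.normal(0.0, 1.0, size=(len(genes), len(samples)))
    expr = pd.DataFrame(x, index=genes, columns=samples)
    shifted = immune_genes + tme_genes  # the immune compendium
    for j, (sample, group) in enumerate(zip(samples, groups)):
        expr.iloc[: len(shifted), j] += spec.immune_shift[group]
    signatures = {
        "immune_core": immune_genes,
        "tis_like": immune_genes[:20],
        "control_random": filler[:30],
    }
    return expr, signatures, tme_reference, immune_genes


def _simulate_metabolites(rng, samples, groups, spec: CohortSpec, kind: str):
    if kind == "metabolite":
        pathways = {p: [f"met_{p.split()[0].lower()[:6]}_{i:02d}" for i in range(10)] for p in LIPID_PATHWAYS + OTHER_PATHWAYS}
        annotation = pd.DataFrame(
            [
                {"feature": f, "pathway": p, "category": "lipid" if p in LIPID_PATHWAYS else "other"}
                for p, feats in pathways.items()
                for f in feats
            ]
        )
        shifted = annotation.loc[annotation["category"] == "lipid", "feature"].tolist()
        prefix = "met"
    else:
        rows = []
        for cat, mains in _LIPID_CLASSES.items():
            for main in mains:
                for i in range(40):
                    rows.append({"feature": f"lip_{main}_{i:02d}", "category": cat, "main_class": main})
        annotation = pd.DataFrame(rows)
        shifted = annotation.loc[annotation["main_class"].isin(SHIFTED_LIPID_CLASSES), "feature"].tolist()
        prefix = "lip"
    features = annotation["feature"].unique().tolist()
    base = rng.normal(15.0, 2.0, size=len(features))
    # tumor-normal differences planted on 60% of features so the prefilter bites
    is_diff = rng.random(len(features)) < 0.6
    delta = np.where(is_diff, rng.choice([-2.0, 2.0], size=len(features)), 0.0)
    tumor = base[:, None] + rng.normal(0.0, 1.0, size=(len(features), len(samples)))
    normal = (base - delta)[:, None] + rng.normal(0.0, 1.0, size=(len(features), len(samples)))
    tumor = pd.DataFrame(tumor, index=features, columns=samples)
    normal_cols = [f"{s}_N" for s in samples]
    normal = pd.DataFrame(normal, index=features, columns=normal_cols)
    shift_mask = tumor.index.isin(shifted)
    for j, (sample, group) in enumerate(zip(samples, groups)):
        tumor.iloc[shift_mask.nonzero()[0], j] += spec.lipid_shift[group]
    truth = {"shifted_features": shifted, "tumor_normal_diff": [f for f, d in zip(features, is_diff) if d], "prefix": prefix}
    return tumor, normal, annotation, truth


def generate_survival(
    cohort: pd.DataFrame,
    hazard_ratio: dict | float,
    censor_rate: float,
    seed: int | np.random.Generator,
    baseline_hazard: float = 0.004,
) -> pd.DataFrame:
    """Populate OS/DMFS/RFS times (months) and event flags.

    Death times are exponential with a per-group proportional hazard on the
    baseline rate. A sample is censored with probability ``censor_rate``; its
    censoring time is uniform on (0, earliest event time), so ``censor_rate=1``
    yields zero events on every endpoint. Relapse and distant metastasis
    precede death for a random subset, keeping RFS time <= OS time always.
    """
    if not (0.0 <= censor_rate <= 1.0):
        raise ValueError("censor_rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hr = _per_group(hazard_ratio, "hazard_ratio")
    out = cohort.copy()
    n = len(out)
    rates = out["group"].map(lambda g: baseline_hazard * hr[g]).to_numpy(dtype=float)
    t_death = rng.exponential(1.0 / rates)
    has_relapse = rng.random(n) < 0.5
    t_relapse = np.where(has_relapse, t_death * rng.uniform(0.3, 1.0, size=n), t_death)
    has_met = rng.random(n) < 0.4
    t_met = np.where(has_met, t_death * rng.uniform(0.3, 1.0, size=n), np.inf)
    censored = rng.random(n) < censor_rate
    earliest = np.minimum(np.minimum(t_death, t_relapse), np.where(np.isfinite(t_met), t_met, t_death))
    t_cens = np.where(censored, earliest * rng.uniform(0.0, 1.0, size=n), np.inf)

    os_time = np.minimum(t_death, t_cens)
    os_event = (~censored).astype(int)
    rfs_raw = np.minimum(t_relapse, t_death)
    rfs_time = np.minimum(rfs_raw, t_cens)
    rfs_event = (rfs_raw <= t_cens).astype(int)
    dmfs_raw = t_met
    dmfs_stop = np.minimum(t_death, t_cens)  # death without metastasis censors DMFS
    dmfs_event = (dmfs_raw <= dmfs_stop).astype(int)
    dmfs_time = np.where(dmfs_event == 1, dmfs_raw, dmfs_stop)

    os_time, rfs_time, dmfs_time = (np.maximum(t, 0.01) for t in (os_time, rfs_time, dmfs_time))
    out["os_months"] = np.round(os_time, 2)
    out["os_event"] = os_event
    out["rfs_months"] = np.round(rfs_time, 2)
    out["rfs_event"] = rfs_event
    out["dmfs_months"] = np.round(dmfs_time, 2)
    out["dmfs_event"] = dmfs_event
    return out


def generate_cohort(spec: CohortSpec, build: GenomeBuild | None = None) -> SyntheticCohort:
    """Generate the full synthetic cohort. Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    build = build or synthetic_build()
    groups = _draw_groups(rng, spec)
    samples = [f"S{i:04d}" for i in range(1, spec.n_samples + 1)]

    n = spec.n_samples
    cohort = pd.DataFrame(
        {
            "sample": samples,
            "group": groups,
            "age": np.clip(np.round(rng.normal(50, 10, n)), 25, 85).astype(int),
            "tumor_size_cat": rng.choice([1, 2, 3], size=n, p=[0.3, 0.5, 0.2]),
            "node_status": rng.choice([0, 1], size=n, p=[0.55, 0.45]),
            "architectural_distortion": [
                int(rng.random() < (0.3 if g == "high_suspicion" else 0.1)) for g in groups
            ],
        }
    )
    cohort = generate_survival(cohort, spec.hazard_ratio, spec.censor_rate, rng, spec.baseline_hazard)

    mutations, pik3ca_truth = _simulate_mutations(rng, samples, groups, spec, build)
    segments, scar_truth = _simulate_segments(rng, samples, groups, spec, build)
    hla_genotypes = _simulate_hla_genotypes(rng, samples)
    expression, signatures, tme_reference, immune_genes = _simulate_expression(rng, samples, groups, spec)
    metab, metab_n, metab_ann, metab_truth = _simulate_metabolites(rng, samples, groups, spec, "metabolite")
    lipid, lipid_n, lipid_ann, lipid_truth = _simulate_metabolites(rng, samples, groups, spec, "lipid")

    truth = {
        "spec": {
            "n_samples": spec.n_samples,
            "seed": spec.seed,
            "group_proportions": spec.group_proportions,
            "mutation_rate": spec.mutation_rate,
            "pik3ca_freq": spec.pik3ca_freq,
            "scar_intensity": spec.scar_intensity,
            "hla_loh_freq": spec.hla_loh_freq,
            "immune_shift": spec.immune_shift,
            "lipid_shift": spec.lipid_shift,
            "hazard_ratio": spec.hazard_ratio,
            "censor_rate": spec.censor_rate,
            "baseline_hazard": spec.baseline_hazard,
        },
        "per_sample": {
            s: {"group": g, "pik3ca": pik3ca_truth[s], **scar_truth[s]}
            for s, g in zip(samples, groups)
        },
        "immune_genes": immune_genes,
        "metabolites": metab_truth,
        "lipids": lipid_truth,
    }
    return SyntheticCohort(
        cohort=cio.validate_cohort(cohort),
        mutations=mutations,
        segments=segments,
        expression=expression,
        metabolites=metab,
        metabolites_normal=metab_n,
        lipids=lipid,
        lipids_normal=lipid_n,
        metabolite_annotation=metab_ann,
        lipid_annotation=lipid_ann,
        signatures=signatures,
        tme_reference=tme_reference,
        hla_genotypes=hla_genotypes,
        build=build,
        truth=truth,
    )
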