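"""Readers and writers for the on-disk formats the pipeline touches.

Tables are exchanged as tab-separated text with 1-based inclusive coordinates;
every writer emits a ``# coordinates=1-based-inclusive`` header comment. All
readers validate rather than coerce: a malformed file raises
:class:`FormatError` naming the offending column, line or cell.

Schemas
-------
MAF-like mutation table (:data:`MAF_COLUMNS`):
    Tumor_Sample_Barcode, Hugo_Symbol, Chromosome, Start_Position,
    Reference_Allele, Tumor_Seq_Allele2, Variant_Classification, and the
    optional Trinucleotide_Context (3-mer centred on the position).
SEG-like allele-specific copy-number table (:data:`SEG_COLUMNS`):
    sample, chromosome, start, end, nMajor, nMinor. Ingest canonicalises
    nMajor >= nMinor by swapping — all scar rules are order-insensitive.
Cohort table (:data:`COHORT_COLUMNS`): one row per patient with the
    calcification group, clinical covariates, and per-endpoint follow-up.
"""

from __future__ import annotations

import pandas as pd

from .genome import GenomeBuild

COORD_HEADER = "# coordinates=1-based-inclusive"

#: Calcification groups, ordered from no calcification to BI-RADS 4C-5.
CALCIFICATION_GROUPS = ("negative", "probably_benign", "low_moderate", "high_suspicion")

#: MAF variant classes counted as nonsynonymous for burden estimation.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Translation_Start_Site",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
    }
)

#: The closed variant-classification vocabulary (nonsynonymous plus silent and
#: common non-coding classes that a caller may carry along).
VARIANT_CLASSES = NONSYNONYMOUS_CLASSES | {
    "Silent",
    "Intron",
    "3'UTR",
    "5'UTR",
    "IGR",
    "RNA",
}

MAF_COLUMNS = [
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
]

SEG_COLUMNS = ["sample", "chromosome", "start", "end", "nMajor", "nMinor"]

COHORT_COLUMNS = [
    "sample",
    "group",
    "age",
    "tumor_size_cat",
    "node_status",
    "architectural_distortion",
    "os_months",
    "os_event",
    "dmfs_months",
    "dmfs_event",
    "rfs_months",
    "rfs_event",
]


class FormatError(ValueError):
    """A file violated its format contract."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing required column(s): {missing}")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"Chromosome": str, "chromosome": str})


def _write_tsv(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mutations (MAF-like)
# ---------------------------------------------------------------------------

def validate_mutations(df: pd.DataFrame, build: GenomeBuild | None = None) -> pd.DataFrame:
    _require_columns(df, MAF_COLUMNS, "mutation table")
    df = df.copy()
    df["Chromosome"] = df["Chromosome"].astype(str)
    df["Start_Position"] = df["Start_Position"].astype(int)
    if (df["Start_Position"] < 1).any():
        raise FormatError("mutation table has positions < 1 (coordinates are 1-based)")
    same = df["Reference_Allele"] == df["Tumor_Seq_Allele2"]
    if same.any():
        raise FormatError(f"{int(same.sum())} mutation row(s) have ref == alt")
    bad_class = ~df["Variant_Classification"].isin(VARIANT_CLASSES)
    if bad_class.any():
        unknown = sorted(df.loc[bad_class, "Variant_Classification"].unique())
        raise FormatError(f"unknown Variant_Classification value(s): {unknown}")
    if build is not None:
        bad_chrom = ~df["Chromosome"].isin(build.names)
        if bad_chrom.any():
            unknown = sorted(df.loc[bad_chrom, "Chromosome"].unique())
            raise FormatError(f"unknown chromosome(s) vs. genome build: {unknown}")
    df["is_nonsynonymous"] = df["Variant_Classification"].isin(NONSYNONYMOUS_CLASSES)
    return df


def read_maf(path, build: GenomeBuild | None = None) -> pd.DataFrame:
    """Read a MAF-like TSV of somatic mutations.

    Returns the validated table with an ``is_nonsynonymous`` column added
    (the TMB vocabulary: missense, nonsense, nonstop, splice site,
    translation start site, in-frame and frameshift indels).
    """
    return validate_mutations(_read_tsv(path), build=build)


def write_maf(df: pd.DataFrame, path) -> None:
    cols = [c for c in MAF_COLUMNS + ["Trinucleotide_Context"] if c in df.columns]
    _write_tsv(df[cols], path)


# ---------------------------------------------------------------------------
# allele-specific segments (SEG-like)
# ---------------------------------------------------------------------------

def validate_segments(df: pd.DataFrame, build: GenomeBuild | None = None) -> pd.DataFrame:
    _require_columns(df, SEG_COLUMNS, "segment table")
    df = df.copy()
    for col in ("start", "end", "nMajor", "nMinor"):
        df[col] = df[col].astype(int)
    df["chromosome"] = df["chromosome"].astype(str)
    if (df["end"] < df["start"]).any():
        bad = df.index[df["end"] < df["start"]].tolist()
        raise FormatError(f"segment end < start at row(s) {bad}")
    if (df[["nMajor", "nMinor"]] < 0).any().any():
        raise FormatError("negative allele copy numbers")
    # canonical allele ordering: nMajor >= nMinor, swapping on ingest
    swap = df["nMajor"] < df["nMinor"]
    if swap.any():
        lo = df.loc[swap, "nMajor"].copy()
        df.loc[swap, "nMajor"] = df.loc[swap, "nMinor"]
        df.loc[swap, "nMinor"] = lo
    if build is not None:
        bad_chrom = ~df["chromosome"].isin(build.names)
        if bad_chrom.any():
            unknown = sorted(df.loc[bad_chrom, "chromosome"].unique())
            raise FormatError(f"unknown chromosome(s) vs. genome build: {unknown}")
    df = df.sort_values(["sample", "chromosome", "start"], kind="mergesort").reset_index(drop=True)
    # per-sample, per-chromosome non-overlap (1-based inclusive coordinates)
    for (sample, chrom), grp in df.groupby(["sample", "chromosome"], sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        overlap = starts[1:] <= ends[:-1]
        if overlap.any():
            offenders = grp.iloc[:-1][overlap][["start", "end"]].values.tolist()
            raise FormatError(
                f"overlapping segments for sample {sample!r} chromosome {chrom!r}: "
                f"segments ending at {offenders} overlap their successors"
            )
    return df


def read_segments(path, build: GenomeBuild | None = None) -> pd.DataFrame:
    """Read allele-specific copy-number segments (sample, chromosome, start,
    end, nMajor, nMinor; 1-based inclusive). Segments are returned sorted,
    non-overlapping per sample/chromosome, with nMajor >= nMinor enforced."""
    return validate_segments(_read_tsv(path), build=build)


def write_segments(df: pd.DataFrame, path) -> None:
    _write_tsv(df[SEG_COLUMNS], path)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: one set per line, tab-separated
    name/description/members. Duplicate members are dropped (first kept);
    an empty member list is rejected."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            name, _desc, *members = fields
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if not deduped:
                raise FormatError(f"GMT line {lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate gene-set name {name!r}")
            sets[name] = deduped
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# feature x sample matrices
# ---------------------------------------------------------------------------

def read_matrix(path, na_policy: str = "error") -> pd.DataFrame:
    """Read a feature x sample TSV matrix (first column = feature id, header
    row = sample ids).

    na_policy: 'error' (default) rejects missing values, 'drop' removes
    features with any NA, 'impute_min' fills NAs with the feature minimum.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"duplicate feature id(s): {dups}")
    if df.columns.duplicated().any():
        raise FormatError("duplicate sample id(s) in matrix header")
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                feat = df.index[bad][0]
                raise FormatError(f"non-numeric cell at feature {feat!r}, sample {col!r}") from None
        raise
    if df.isna().any().any():
        if na_policy == "error":
            feat = df.index[df.isna().any(axis=1)][0]
            raise FormatError(f"missing value(s), first at feature {feat!r} (na_policy='error')")
        if na_policy == "drop":
            df = df.dropna(axis=0)
        elif na_policy == "impute_min":
            df = df.apply(lambda row: row.fillna(row.min()), axis=1)
        else:
            raise ValueError(f"unknown na_policy {na_policy!r}")
    return df


def write_matrix(df: pd.DataFrame, path, index_label: str = "feature") -> None:
    with open(path, "w") as fh:
        fh.write(COORD_HEADER + "\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


# ---------------------------------------------------------------------------
# GISTIC thresholded calls
# ---------------------------------------------------------------------------

GISTIC_CALLS = (-2, -1, 0, 1, 2)


def read_gistic_thresholded(path) -> pd.DataFrame:
    """Read a GISTIC ``all_thresholded.by_genes``-style matrix (gene rows,
    sample columns, calls in {-2..2}). Amplification is +2 and deep deletion
    is -2; -1/+1 are shallow loss/gain and never count as events."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    # real GISTIC output carries locus/cytoband annotation columns; drop them
    for meta in ("Locus ID", "Cytoband", "Locus_ID"):
        if meta in df.columns:
            df = df.drop(columns=meta)
    df = df.astype(int)
    bad = ~df.isin(GISTIC_CALLS)
    if bad.any().any():
        gene = df.index[bad.any(axis=1)][0]
        raise FormatError(f"GISTIC call outside {{-2..2}} at gene {gene!r}")
    return df


def gistic_events(calls: pd.DataFrame, kind: str = "amplification") -> pd.DataFrame:
    """Binary event matrix from thresholded calls: 'amplification' selects +2,
    'deep_deletion' selects -2."""
    if kind == "amplification":
        return (calls == 2).astype(int)
    if kind == "deep_deletion":
        return (calls == -2).astype(int)
    raise ValueError(f"unknown event kind {kind!r}")


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ["sample", "group"], "cohort table")
    df = df.copy()
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise FormatError(f"duplicate sample id(s) in cohort table: {dups}")
    bad = ~df["group"].isin(CALCIFICATION_GROUPS)
    if bad.any():
        unknown = sorted(df.loc[bad, "group"].unique())
        raise FormatError(
            f"unknown calcification group(s) {unknown}; expected one of {CALCIFICATION_GROUPS}"
        )
    for col in ("os_months", "dmfs_months", "rfs_months"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise FormatError(f"negative follow-up time in column {col!r}")
    return df


def read_cohort(path) -> pd.DataFrame:
    return validate_cohort(_read_tsv(path))


def write_cohort(df: pd.DataFrame, path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    _write_tsv(df[cols], path)
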