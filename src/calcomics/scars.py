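"""Genome-instability scar scores from allele-specific copy-number segments.

The homologous-recombination-deficiency (HRD) score is the sum of three
independent counts computed per sample from ASCAT-style (nMajor, nMinor)
segments:

* **NtAI** — telomeric allelic imbalance: subchromosomal imbalance runs longer
  than 11 Mb that extend to a telomere (at most one per telomere, never a
  whole-chromosome event).
* **LOH** — loss-of-heterozygosity runs longer than 15 Mb but shorter than the
  whole chromosome; runs on chromosome 17 are excluded.
* **LST** — large-scale state transitions: breakpoints whose two flanking
  copy-number regions are each longer than 10 Mb, counted after smoothing away
  segments shorter than 3 Mb.

All "longer than" thresholds are strict. Runs are maximal blocks of abutting
segments sharing the relevant property; a gap between segments breaks a run.
LST is evaluated per chromosome arm when the genome build carries centromeres
(the classical definition), per whole chromosome otherwise.

HLA class-I status is called from the same segments: germline homogeneity from
the 4-digit genotype, and tumor HLA-I LOH when any segment overlapping an
HLA-A/B/C locus has a minor allele copy number of zero.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .genome import MB, GenomeBuild


@dataclass(frozen=True)
class HrdComponents:
    sample: str
    ntai: int
    loh: int
    lst: int

    @property
    def hrd(self) -> int:
        return self.ntai + self.loh + self.lst

    def __post_init__(self) -> None:
        if min(self.ntai, self.loh, self.lst) < 0:
            raise ValueError("scar components must be non-negative")


@dataclass(frozen=True)
class HlaStatus:
    sample: str
    germline: str  # homogeneous | heterogeneous
    tumor_loh: str  # loh | non_loh | indeterminate


def _sample_chrom_segments(segments: pd.DataFrame, chrom: str) -> pd.DataFrame:
    return segments[segments["chromosome"] == chrom].sort_values("start")


def _runs(flags, starts, ends):
    """Maximal runs of consecutive abutting True segments.

    Yields (run_start, run_end) for each maximal block of segments where the
    flag holds and each segment starts exactly one bp after its predecessor
    ends.
    """
    run_start = None
    prev_end = None
    for flag, s, e in zip(flags, starts, ends):
        abutting = prev_end is not None and s == prev_end + 1
        if flag:
            if run_start is None or not abutting:
                if run_start is not None:
                    yield run_start, prev_end
                run_start = s
        else:
            if run_start is not None:
                yield run_start, prev_end
                run_start = None
        prev_end = e
    if run_start is not None:
        yield run_start, prev_end


def compute_ntai(
    segments: pd.DataFrame,
    build: GenomeBuild,
    min_len_mb: float = 11.0,
    include_loh: bool = True,
) -> int:
    """Count telomeric allelic-imbalance regions for one sample.

    A region counts when it is a maximal imbalance run (nMajor != nMinor;
    ``include_loh=False`` additionally requires nMinor > 0) that touches
    coordinate 1 or the chromosome end, is strictly longer than ``min_len_mb``,
    and does not span the whole chromosome. Each chromosome can contribute at
    most two regions, one per telomere.
    """
    min_len = min_len_mb * MB
    count = 0
    for chrom in segments["chromosome"].unique():
        length = build.length(chrom)
        seg = _sample_chrom_segments(segments, chrom)
        imbalanced = seg["nMajor"] != seg["nMinor"]
        if not include_loh:
            imbalanced &= seg["nMinor"] > 0
        for run_start, run_end in _runs(imbalanced.to_numpy(), seg["start"].to_numpy(), seg["end"].to_numpy()):
            if run_start == 1 and run_end == length:
                continue  # whole-chromosome imbalance is not subchromosomal
            touches = (run_start == 1) or (run_end == length)
            if touches and (run_end - run_start + 1) > min_len:
                count += 1
    return count


def compute_loh_score(
    segments: pd.DataFrame,
    build: GenomeBuild,
    min_len_mb: float = 15.0,
    excluded_chromosomes: frozenset[str] = frozenset({"17", "chr17"}),
) -> int:
    """Count LOH runs (nMinor == 0, nMajor > 0) strictly longer than
    ``min_len_mb`` but shorter than the whole chromosome, excluding the listed
    chromosomes (chromosome 17 by convention)."""
    min_len = min_len_mb * MB
    count = 0
    for chrom in segments["chromosome"].unique():
        if chrom in excluded_chromosomes:
            continue
        length = build.length(chrom)
        seg = _sample_chrom_segments(segments, chrom)
        is_loh = (seg["nMinor"] == 0) & (seg["nMajor"] > 0)
        for run_start, run_end in _runs(is_loh.to_numpy(), seg["start"].to_numpy(), seg["end"].to_numpy()):
            run_len = run_end - run_start + 1
            if run_len > min_len and not (run_start == 1 and run_end == length):
                count += 1
    return count


def _merge_identical(states):
    merged: list[list[int]] = []
    for seg in states:
        if merged and merged[-1][2] == seg[2] and merged[-1][3] == seg[3] and seg[0] == merged[-1][1] + 1:
            merged[-1][1] = seg[1]
        else:
            merged.append(list(seg))
    return merged


def _smooth_states(states: list[tuple[int, int, int, int]], smooth_len: int):
    """Merge identical abutting states, drop segments shorter than
    ``smooth_len`` (closing the gap by extending the left neighbour, or the
    right neighbour for a leading short segment), then merge again.

    Merging precedes dropping so that subdividing a segment into
    identical-state pieces never changes the result.

    ``states`` is a list of (start, end, nMajor, nMinor) sorted by start.
    """
    kept: list[list[int]] = []
    pending: list[int] | None = None  # span of dropped segment(s) awaiting a right neighbour
    for s, e, a, b in _merge_identical(states):
        if (e - s + 1) < smooth_len:
            if kept and kept[-1][1] + 1 == s:
                kept[-1][1] = e  # absorbed by the left neighbour
            elif pending is not None and pending[1] + 1 == s:
                pending[1] = e
            else:
                pending = [s, e]
        else:
            if pending is not None and pending[1] + 1 == s:
                s = pending[0]  # leading short run absorbed by its right neighbour
            pending = None
            kept.append([s, e, a, b])
    return [tuple(x) for x in _merge_identical(kept)]


def compute_lst(
    segments: pd.DataFrame,
    build: GenomeBuild,
    min_flank_mb: float = 10.0,
    smooth_mb: float = 3.0,
    per_arm: bool = True,
) -> int:
    """Count large-scale state transitions for one sample.

    Segments shorter than ``smooth_mb`` are smoothed away, identical adjacent
    states merged, and each breakpoint between two abutting regions counts when
    both flanks are strictly longer than ``min_flank_mb``. With
    ``per_arm=True`` (default) segments are clipped to chromosome arms before
    counting, so centromere-crossing breakpoints never count.
    """
    min_flank = min_flank_mb * MB
    smooth_len = smooth_mb * MB
    count = 0
    for chrom in segments["chromosome"].unique():
        seg = _sample_chrom_segments(segments, chrom)
        intervals = build.arms(chrom) if per_arm else [(1, build.length(chrom))]
        for lo, hi in intervals:
            clipped = []
            for s, e, a, b in seg[["start", "end", "nMajor", "nMinor"]].itertuples(index=False):
                cs, ce = max(s, lo), min(e, hi)
                if cs <= ce:
                    clipped.append((cs, ce, a, b))
            smoothed = _smooth_states(clipped, smooth_len)
            for left, right in zip(smoothed, smoothed[1:]):
                if right[0] != left[1] + 1:
                    continue  # gap, not a breakpoint
                left_len = left[1] - left[0] + 1
                right_len = right[1] - right[0] + 1
                if left_len > min_flank and right_len > min_flank:
                    count += 1
    return count


def compute_hrd(
    segments: pd.DataFrame,
    build: GenomeBuild,
    sample: str | None = None,
    **kwargs,
) -> HrdComponents:
    """NtAI + LOH + LST for one sample's segments.

    Keyword arguments are routed to the component functions (``min_len_mb``
    etc. must then be passed via ``ntai_kwargs``/``loh_kwargs``/``lst_kwargs``).
    """
    ntai_kwargs = kwargs.pop("ntai_kwargs", {})
    loh_kwargs = kwargs.pop("loh_kwargs", {})
    lst_kwargs = kwargs.pop("lst_kwargs", {})
    if kwargs:
        raise TypeError(f"unexpected keyword argument(s): {sorted(kwargs)}")
    if sample is None:
        ids = segments["sample"].unique()
        if len(ids) != 1:
            raise ValueError("segments contain multiple samples; pass sample=")
        sample = ids[0]
    seg = segments[segments["sample"] == sample]
    return HrdComponents(
        sample=sample,
        ntai=compute_ntai(seg, build, **ntai_kwargs),
        loh=compute_loh_score(seg, build, **loh_kwargs),
        lst=compute_lst(seg, build, **lst_kwargs),
    )


def hrd_table(segments: pd.DataFrame, build: GenomeBuild, **kwargs) -> pd.DataFrame:
    """Per-sample scar components as a tidy table (sample, ntai, loh, lst, hrd)."""
    rows = []
    for sample in segments["sample"].unique():
        comp = compute_hrd(segments, build, sample=sample, **kwargs)
        rows.append(
            {"sample": comp.sample, "ntai": comp.ntai, "loh": comp.loh, "lst": comp.lst, "hrd": comp.hrd}
        )
    return pd.DataFrame(rows, columns=["sample", "ntai", "loh", "lst", "hrd"])


# ---------------------------------------------------------------------------
# HLA class-I status
# ---------------------------------------------------------------------------

_ALLELE_RE = re.compile(r"^[A-Z]\*\d{2}:\d{2}$")


def call_hla_status(
    sample: str,
    genotypes: dict[str, tuple[str, str]],
    segments: pd.DataFrame,
    hla_loci: dict[str, tuple[str, int, int]],
) -> HlaStatus:
    """Call germline homogeneity and tumor HLA-I LOH for one sample.

    genotypes maps each class-I locus (HLA-A/B/C) to its two 4-digit alleles,
    e.g. ``("A*02:01", "A*11:01")``. Germline is *homogeneous* when any locus
    carries two identical alleles. Tumor LOH is called when any segment
    overlapping any locus interval has nMinor == 0; *indeterminate* when no
    segment covers a locus.
    """
    for locus, alleles in genotypes.items():
        if len(alleles) != 2:
            raise ValueError(f"{locus}: expected exactly two alleles, got {alleles!r}")
        for allele in alleles:
            if not _ALLELE_RE.match(allele):
                raise ValueError(f"{locus}: malformed 4-digit allele {allele!r}")
    germline = (
        "homogeneous"
        if any(a == b for a, b in genotypes.values())
        else "heterogeneous"
    )
    seg = segments[segments["sample"] == sample] if "sample" in segments.columns else segments
    any_loh = False
    any_covered = False
    for locus, (chrom, lo, hi) in hla_loci.items():
        over = seg[(seg["chromosome"] == chrom) & (seg["start"] <= hi) & (seg["end"] >= lo)]
        if len(over):
            any_covered = True
            if (over["nMinor"] == 0).any():
                any_loh = True
    if any_loh:
        tumor = "loh"
    elif any_covered:
        tumor = "non_loh"
    else:
        tumor = "indeterminate"
    return HlaStatus(sample=sample, germline=germline, tumor_loh=tumor)
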