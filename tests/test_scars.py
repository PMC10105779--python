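"""Genome-instability scar scores, checked by hand-worked examples and an
independent per-megabase brute-force re-derivation on random genomes."""

import numpy as np
import pytest

from calcomics import (
    GenomeBuild,
    call_hla_status,
    compute_hrd,
    compute_loh_score,
    compute_lst,
    compute_ntai,
)
from calcomics.genome import MB
from calcomics.io import validate_segments

from conftest import make_segments

CHR100 = GenomeBuild(chromosomes={"chr1": 100 * MB})


def seg(rows, build=None):
    return validate_segments(make_segments(rows), build=build)


# ---------------------------------------------------------------------------
# hand-worked examples
# ---------------------------------------------------------------------------

class TestNtai:
    def test_balanced_genome_zero(self):
        s = seg([("chr1", 1, 100 * MB, 1, 1)])
        assert compute_ntai(s, CHR100) == 0

    def test_p_telomeric_12mb_imbalance_counts(self):
        s = seg([("chr1", 1, 12 * MB, 2, 1), ("chr1", 12 * MB + 1, 100 * MB, 1, 1)])
        assert compute_ntai(s, CHR100) == 1

    def test_whole_chromosome_imbalance_excluded(self):
        s = seg([("chr1", 1, 100 * MB, 2, 1)])
        assert compute_ntai(s, CHR100) == 0

    def test_strictly_longer_than_11mb(self):
        s = seg([("chr1", 1, 11 * MB, 2, 1), ("chr1", 11 * MB + 1, 100 * MB, 1, 1)])
        assert compute_ntai(s, CHR100) == 0

    def test_interstitial_imbalance_not_counted(self):
        s = seg(
            [
                ("chr1", 1, 20 * MB, 1, 1),
                ("chr1", 20 * MB + 1, 40 * MB, 2, 1),
                ("chr1", 40 * MB + 1, 100 * MB, 1, 1),
            ]
        )
        assert compute_ntai(s, CHR100) == 0

    def test_loh_exclusion_toggle(self):
        s = seg([("chr1", 1, 20 * MB, 1, 0), ("chr1", 20 * MB + 1, 100 * MB, 1, 1)])
        assert compute_ntai(s, CHR100) == 1
        assert compute_ntai(s, CHR100, include_loh=False) == 0


class TestLohScore:
    def test_20mb_run_counts(self):
        s = seg([("chr1", 1, 30 * MB, 1, 1), ("chr1", 30 * MB + 1, 50 * MB, 1, 0), ("chr1", 50 * MB + 1, 100 * MB, 1, 1)])
        assert compute_loh_score(s, CHR100) == 1

    def test_chr17_excluded(self):
        b = GenomeBuild(chromosomes={"chr17": 100 * MB})
        s = seg([("chr17", 1, 30 * MB, 1, 1), ("chr17", 30 * MB + 1, 50 * MB, 1, 0), ("chr17", 50 * MB + 1, 100 * MB, 1, 1)])
        assert compute_loh_score(s, b) == 0

    def test_whole_chromosome_loh_excluded(self):
        s = seg([("chr1", 1, 100 * MB, 2, 0)])
        assert compute_loh_score(s, CHR100) == 0

    def test_homozygous_deletion_is_not_loh(self):
        s = seg([("chr1", 1, 30 * MB, 1, 1), ("chr1", 30 * MB + 1, 50 * MB, 0, 0), ("chr1", 50 * MB + 1, 100 * MB, 1, 1)])
        assert compute_loh_score(s, CHR100) == 0


class TestLst:
    def test_single_segment_zero(self):
        s = seg([("chr1", 1, 100 * MB, 2, 1)])
        assert compute_lst(s, CHR100) == 0

    def test_short_second_flank_gives_one_breakpoint(self):
        # 40 Mb (2,1) | 50 Mb (2,0) | 10 Mb (2,2): only the first breakpoint
        # has both flanks strictly longer than 10 Mb
        s = seg(
            [
                ("chr1", 1, 40 * MB, 2, 1),
                ("chr1", 40 * MB + 1, 90 * MB, 2, 0),
                ("chr1", 90 * MB + 1, 100 * MB, 2, 2),
            ]
        )
        assert compute_lst(s, CHR100) == 1

    def test_smoothing_removes_small_insert(self):
        base = seg([("chr1", 1, 50 * MB, 1, 1), ("chr1", 50 * MB + 1, 100 * MB, 2, 1)])
        with_insert = seg(
            [
                ("chr1", 1, 20 * MB, 1, 1),
                ("chr1", 20 * MB + 1, 22 * MB, 3, 1),  # 2 Mb blip inside uniform region
                ("chr1", 22 * MB + 1, 50 * MB, 1, 1),
                ("chr1", 50 * MB + 1, 100 * MB, 2, 1),
            ]
        )
        assert compute_lst(with_insert, CHR100) == compute_lst(base, CHR100) == 1

    def test_centromere_crossing_breakpoint_not_counted_per_arm(self):
        b = GenomeBuild(chromosomes={"chr1": 100 * MB}, centromeres={"chr1": (50 * MB + 1, 50 * MB + 2)})
        s = seg([("chr1", 1, 50 * MB, 1, 1), ("chr1", 50 * MB + 1, 100 * MB, 2, 1)])
        assert compute_lst(s, b, per_arm=True) == 0
        assert compute_lst(s, b, per_arm=False) == 1


def test_hrd_is_component_sum(small_cohort):
    segs = small_cohort.segments
    sample = segs["sample"].iloc[0]
    comp = compute_hrd(segs, small_cohort.build, sample=sample)
    one = segs[segs["sample"] == sample]
    assert comp.hrd == (
        compute_ntai(one, small_cohort.build)
        + compute_loh_score(one, small_cohort.build)
        + compute_lst(one, small_cohort.build)
    )
    assert compute_hrd(seg([("chr1", 1, 100 * MB, 1, 1)]), CHR100).hrd == 0


# ---------------------------------------------------------------------------
# brute-force oracle on random genomes
# ---------------------------------------------------------------------------

def _oracle_scores(segments, build, excluded=()):
    """Independent re-derivation from a per-megabase state expansion."""
    ntai = loh = lst = 0
    for chrom in segments["chromosome"].unique():
        length_mb = build.length(chrom) // MB
        state = np.full((length_mb, 2), -1, dtype=int)
        for _, row in segments[segments["chromosome"] == chrom].iterrows():
            lo = (row["start"] - 1) // MB
            hi = row["end"] // MB
            state[lo:hi] = (row["nMajor"], row["nMinor"])

        def runs(flag):
            out, start = [], None
            for i, f in enumerate(flag):
                if f and start is None:
                    start = i
                if not f and start is not None:
                    out.append((start, i - 1))
                    start = None
            if start is not None:
                out.append((start, len(flag) - 1))
            return out

        imb = (state[:, 0] != state[:, 1]) & (state[:, 0] >= 0)
        for a, b in runs(imb):
            n = b - a + 1
            if (a == 0 or b == length_mb - 1) and not (a == 0 and b == length_mb - 1) and n > 11:
                ntai += 1
        if chrom not in excluded:
            lo_flag = (state[:, 1] == 0) & (state[:, 0] > 0)
            for a, b in runs(lo_flag):
                n = b - a + 1
                if n > 15 and not (a == 0 and b == length_mb - 1):
                    loh += 1
        # LST per arm from run-length encoding of the state array
        for arm_lo, arm_hi in build.arms(chrom):
            arr = state[(arm_lo - 1) // MB : arm_hi // MB]
            rle = []
            for s in arr:
                t = tuple(s)
                if rle and rle[-1][0] == t:
                    rle[-1][1] += 1
                else:
                    rle.append([t, 1])
            # smoothing: a short run's span is absorbed by its left neighbour
            # (right neighbour at the arm start), then identical states merge
            smoothed, carry = [], 0
            for t, n in rle:
                if n < 3:
                    if smoothed:
                        smoothed[-1][1] += n
                    else:
                        carry += n
                else:
                    smoothed.append([t, n + carry])
                    carry = 0
            merged = []
            for t, n in smoothed:
                if merged and merged[-1][0] == t:
                    merged[-1][1] += n
                else:
                    merged.append([t, n])
            for (t1, n1), (t2, n2) in zip(merged, merged[1:]):
                if n1 > 10 and n2 > 10:
                    lst += 1
    return ntai, loh, lst


def _random_profile(rng, build):
    rows = []
    for chrom in build.names:
        length_mb = build.length(chrom) // MB
        n_bp = rng.integers(0, 8)
        cuts = np.unique(rng.integers(1, length_mb, size=n_bp))
        bounds = [0, *cuts, length_mb]
        for lo, hi in zip(bounds, bounds[1:]):
            major = int(rng.integers(0, 4))
            minor = int(rng.integers(0, major + 1))
            rows.append((chrom, lo * MB + 1, hi * MB, major, minor))
    return seg(rows, build=build)


@pytest.mark.parametrize("rep", range(4))
def test_hrd_matches_bruteforce_on_random_profiles(rep, build):
    """NtAI/LOH/LST equal an independent per-Mb re-derivation (200 profiles)."""
    rng = np.random.default_rng(1000 + rep)
    for _ in range(50):
        segs = _random_profile(rng, build)
        comp = compute_hrd(segs, build)
        assert (comp.ntai, comp.loh, comp.lst) == _oracle_scores(segs, build)


def test_scores_invariant_under_segment_subdivision(build, rng):
    """Splitting any segment into identical-state pieces changes nothing."""
    for rep in range(20):
        segs = _random_profile(np.random.default_rng(rep), build)
        split_rows = []
        for _, r in segs.iterrows():
            mid_lo = (r["start"] + r["end"]) // 2
            if np.random.default_rng(rep).random() < 0.5 and mid_lo > r["start"]:
                split_rows.append((r["chromosome"], r["start"], mid_lo, r["nMajor"], r["nMinor"]))
                split_rows.append((r["chromosome"], mid_lo + 1, r["end"], r["nMajor"], r["nMinor"]))
            else:
                split_rows.append((r["chromosome"], r["start"], r["end"], r["nMajor"], r["nMinor"]))
        split = seg(split_rows, build=build)
        a, b = compute_hrd(segs, build), compute_hrd(split, build)
        assert (a.ntai, a.loh, a.lst) == (b.ntai, b.loh, b.lst)


# ---------------------------------------------------------------------------
# HLA status
# ---------------------------------------------------------------------------

class TestHla:
    LOCI = {"HLA-A": ("chr6", 29 * MB, 30 * MB), "HLA-B": ("chr6", 31 * MB, 32 * MB)}
    B = GenomeBuild(chromosomes={"chr6": 100 * MB})

    def geno(self, a1="A*02:01", a2="A*11:01"):
        return {"HLA-A": (a1, a2), "HLA-B": ("B*07:02", "B*08:01")}

    def test_homogeneous_when_any_locus_identical(self):
        s = seg([("chr6", 1, 100 * MB, 2, 1)])
        st = call_hla_status("S1", self.geno("A*02:01", "A*02:01"), s, self.LOCI)
        assert st.germline == "homogeneous"
        st = call_hla_status("S1", self.geno(), s, self.LOCI)
        assert st.germline == "heterogeneous"

    def test_loh_over_single_locus(self):
        s = seg(
            [
                ("chr6", 1, 30 * MB + 500, 2, 1),
                ("chr6", 30 * MB + 501, 33 * MB, 1, 0),  # covers HLA-B only
                ("chr6", 33 * MB + 1, 100 * MB, 2, 1),
            ]
        )
        assert call_hla_status("S1", self.geno(), s, self.LOCI).tumor_loh == "loh"

    def test_non_loh_and_indeterminate(self):
        covered = seg([("chr6", 1, 100 * MB, 2, 1)])
        assert call_hla_status("S1", self.geno(), covered, self.LOCI).tumor_loh == "non_loh"
        uncovered = seg([("chr6", 50 * MB, 100 * MB, 2, 1)])
        assert call_hla_status("S1", self.geno(), uncovered, self.LOCI).tumor_loh == "indeterminate"

    def test_malformed_genotype_rejected(self):
        s = seg([("chr6", 1, 100 * MB, 2, 1)])
        with pytest.raises(ValueError, match="malformed"):
            call_hla_status("S1", {"HLA-A": ("A*2:1", "A*02:01")}, s, self.LOCI)

    def test_planted_loh_recall_and_false_positive_rate(self, small_cohort):
        """Recall 1.0 and FPR 0.0 on noise-free planted HLA LOH."""
        truth = small_cohort.truth["per_sample"]
        for sample, info in truth.items():
            segs = small_cohort.segments[small_cohort.segments["sample"] == sample]
            st = call_hla_status(
                sample, small_cohort.hla_genotypes[sample], segs, small_cohort.build.hla_loci
            )
            assert (st.tumor_loh == "loh") == info["hla_loh"]
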