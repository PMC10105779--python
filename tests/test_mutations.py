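import numpy as np
import pandas as pd
import pytest

from calcomics import (
    build_sbs96,
    classify_clustered_mutations,
    compute_tmb,
    filter_neoantigens,
    imd_threshold,
    refit_signatures,
)
from calcomics.mutations import SBS96_CLASSES, sbs96_class

from conftest import make_mutations


def muts(rows):
    return make_mutations(rows)


def snv_rows(sample, positions, chrom="chr1", ref="C", alt="T", ctx="ACA"):
    return [(sample, chrom, p, ref, alt, "Missense_Mutation", ctx) for p in positions]


# ---------------------------------------------------------------------------
# TMB
# ---------------------------------------------------------------------------

class TestTmb:
    def test_zero_mutations(self):
        df = muts([]).astype({"Start_Position": int})
        assert compute_tmb(df).empty

    def test_printed_footprint(self):
        df = muts(snv_rows("S1", range(1000, 1100)))
        tmb = compute_tmb(df)
        assert tmb["S1"] == pytest.approx(100 / 35.618)
        assert tmb["S1"] == pytest.approx(2.8076, abs=1e-4)

    def test_silent_mutations_excluded(self):
        nonsyn = muts(snv_rows("S1", range(1000, 1050)))
        silent = muts([("S1", "chr2", p, "C", "T", "Silent", "ACA") for p in range(50)])
        both = pd.concat([nonsyn, silent], ignore_index=True)
        assert compute_tmb(both)["S1"] == compute_tmb(nonsyn)["S1"]

    def test_bad_footprint(self):
        with pytest.raises(ValueError):
            compute_tmb(muts(snv_rows("S1", [10])), footprint_mb=0)


# ---------------------------------------------------------------------------
# IMD threshold + clustering
# ---------------------------------------------------------------------------

class TestImd:
    def test_single_mutation_no_threshold(self, build):
        res = imd_threshold(muts(snv_rows("S1", [100])), build, seed=0)
        assert res.threshold is None

    def test_fixed_seed_deterministic(self, build, rng):
        df = muts(snv_rows("S1", sorted(rng.integers(1, 10**8, size=40))))
        a = imd_threshold(df, build, seed=7)
        b = imd_threshold(df, build, seed=7)
        assert a == b

    def test_runs_requested_number_of_simulations(self, build):
        df = muts(snv_rows("S1", [5_000_000 + 200 * i for i in range(5)]))
        res = imd_threshold(df, build, seed=0)
        assert res.n_simulations == 100  # the calibrated default

    def test_null_catalog_rarely_thresholded(self, build):
        """Uniform catalogs with no planted clusters get a threshold at most
        at about the q-value rate over replicates."""
        hits = 0
        n_rep = 30
        for i in range(n_rep):
            rng = np.random.default_rng(10_000 + i)
            pos = rng.integers(1, 10**8, size=30)
            chroms = [f"chr{c}" for c in rng.integers(1, 11, size=30)]
            df = make_mutations(
                [("S1", c, int(p), "C", "T", "Missense_Mutation", "ACA") for c, p in zip(chroms, pos)]
            )
            if imd_threshold(df, build, seed=i).threshold is not None:
                hits += 1
        assert hits / n_rep <= 0.2  # q_cut 0.1 plus Monte-Carlo slack

    def test_planted_kataegis_found(self, build, rng):
        background = snv_rows("S1", sorted(rng.integers(1, 10**8, size=50)), chrom="chr2")
        cluster = snv_rows("S1", [5_000_000 + 250 * i for i in range(6)])
        df = muts(background + cluster)
        res = imd_threshold(df, build, seed=3)
        assert res.threshold is not None
        calls = classify_clustered_mutations(df, res.threshold)
        assert (calls["cluster_class"] == "kataegis").sum() == 6


class TestClusterClasses:
    def test_adjacent_pair_is_dbs(self):
        calls = classify_clustered_mutations(muts(snv_rows("S1", [100, 101])), threshold=1000)
        assert list(calls["cluster_class"]) == ["DBS", "DBS"]

    def test_adjacent_run_is_mbs(self):
        calls = classify_clustered_mutations(muts(snv_rows("S1", [100, 101, 102])), threshold=1000)
        assert set(calls["cluster_class"]) == {"MBS"}

    def test_three_spread_is_omikli(self):
        calls = classify_clustered_mutations(muts(snv_rows("S1", [100, 150, 210])), threshold=1000)
        assert set(calls["cluster_class"]) == {"omikli"}

    def test_five_spread_is_kataegis(self):
        calls = classify_clustered_mutations(
            muts(snv_rows("S1", [100 + 200 * i for i in range(5)])), threshold=1000
        )
        assert set(calls["cluster_class"]) == {"kataegis"}

    def test_partition_and_order_invariance(self, build, rng):
        """Every mutation gets exactly one class; shuffling input rows changes
        nothing; cross-chromosome IMD is never bridged."""
        rows = []
        for chrom in ("chr1", "chr2"):
            rows += snv_rows("S1", sorted(rng.integers(1, 10**7, size=25)), chrom=chrom)
        df = muts(rows)
        calls = classify_clustered_mutations(df, threshold=50_000)
        assert len(calls) == len(df)
        clustered = calls[calls["cluster_class"] != "non_clustered"]
        assert clustered["cluster_id"].notna().all()
        assert calls.groupby("cluster_id")["Chromosome"].nunique().le(1).all()
        shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
        calls2 = classify_clustered_mutations(shuffled, threshold=50_000)
        key = ["Chromosome", "Start_Position"]
        merged = calls.merge(calls2, on=key, suffixes=("_a", "_b"))
        assert (merged["cluster_class_a"] == merged["cluster_class_b"]).all()


# ---------------------------------------------------------------------------
# SBS96
# ---------------------------------------------------------------------------

def _oracle_sbs96(rows):
    """Independent binning via explicit complement tables."""
    comp = str.maketrans("ACGT", "TGCA")
    counts = dict.fromkeys(SBS96_CLASSES, 0)
    for _s, _c, _p, ref, alt, _v, ctx in rows:
        if ref in "AG":
            ctx = ctx.translate(comp)[::-1]
            ref, alt = ref.translate(comp), alt.translate(comp)
        counts[f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"] += 1
    return pd.Series(counts)


class TestSbs96:
    def test_single_pyrimidine_snv(self):
        cat = build_sbs96(muts(snv_rows("S1", [100], ref="C", alt="A", ctx="ACA")))
        assert cat["A[C>A]A"] == 1 and cat.sum() == 1

    def test_reverse_complement_collapse(self):
        cat = build_sbs96(muts(snv_rows("S1", [100], ref="G", alt="T", ctx="TGT")))
        assert cat["A[C>A]A"] == 1

    def test_total_equals_snv_count_and_non_snvs_ignored(self, rng):
        rows = snv_rows("S1", range(100, 140))
        df = muts(rows)
        indel = muts([("S1", "chr1", 999, "AT", "A", "Frame_Shift_Del", "AAA")])
        cat = build_sbs96(pd.concat([df, indel], ignore_index=True))
        assert cat.sum() == 40

    def test_strand_collapse_symmetry(self, rng):
        """A catalog and its full reverse complement bin identically."""
        bases = "ACGT"
        comp = str.maketrans("ACGT", "TGCA")
        rows, flipped = [], []
        for i in range(100):
            ref = bases[rng.integers(4)]
            alt = [b for b in bases if b != ref][rng.integers(3)]
            ctx = bases[rng.integers(4)] + ref + bases[rng.integers(4)]
            rows.append(("S1", "chr1", 100 + 10 * i, ref, alt, "Missense_Mutation", ctx))
            flipped.append(
                ("S1", "chr1", 100 + 10 * i, ref.translate(comp), alt.translate(comp), "Missense_Mutation", ctx.translate(comp)[::-1])
            )
        pd.testing.assert_series_equal(build_sbs96(muts(rows)), build_sbs96(muts(flipped)))

    def test_matches_bruteforce_on_random_catalogs(self):
        """200 random catalogs agree with an independent binning oracle."""
        bases = "ACGT"
        for rep in range(200):
            rng = np.random.default_rng(rep)
            rows = []
            for i in range(30):
                ref = bases[rng.integers(4)]
                alt = [b for b in bases if b != ref][rng.integers(3)]
                ctx = bases[rng.integers(4)] + ref + bases[rng.integers(4)]
                rows.append(("S1", "chr1", 100 + 10 * i, ref, alt, "Missense_Mutation", ctx))
            pd.testing.assert_series_equal(build_sbs96(muts(rows)), _oracle_sbs96(rows))

    def test_bad_context_rejected(self):
        with pytest.raises(ValueError, match="center"):
            sbs96_class("C", "T", "AAA")
        with pytest.raises(ValueError, match="length"):
            sbs96_class("C", "T", "ACAC")


# ---------------------------------------------------------------------------
# signature refitting
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(123)
    sigs = rng.dirichlet(np.ones(96) * 0.2, size=5)
    return pd.DataFrame(sigs, index=[f"SBS_{i}" for i in range(5)], columns=list(SBS96_CLASSES))


class TestRefit:
    def test_exact_member_recovered(self, reference):
        cat = pd.Series(100 * reference.iloc[2].to_numpy(), index=reference.columns)
        exp = refit_signatures(cat, reference)
        w = exp.exposures / exp.exposures.sum()
        assert w["SBS_2"] > 0.999
        assert exp.reconstruction_error < 1e-8

    def test_two_component_mixture(self, reference):
        cat = pd.Series(
            1000 * (0.6 * reference.iloc[0] + 0.4 * reference.iloc[1]).to_numpy(),
            index=reference.columns,
        )
        exp = refit_signatures(cat, reference)
        w = exp.exposures / exp.exposures.sum()
        assert abs(w["SBS_0"] - 0.6) < 0.05 and abs(w["SBS_1"] - 0.4) < 0.05

    def test_nonnegative_and_error_monotone_in_reference_size(self, reference):
        rng = np.random.default_rng(5)
        cat = pd.Series(rng.poisson(5, size=96).astype(float), index=reference.columns)
        errs = []
        for k in range(1, 6):
            exp = refit_signatures(cat, reference.iloc[:k], sparsity_tol=None)
            assert (exp.exposures >= 0).all()
            errs.append(exp.reconstruction_error)
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_matches_projected_gradient_oracle(self, reference):
        """Solver residual is never worse than an independent projected-gradient
        NNLS on 200 random instances."""
        a = reference.to_numpy().T
        for rep in range(200):
            rng = np.random.default_rng(rep)
            cat = pd.Series(rng.poisson(3, size=96).astype(float), index=reference.columns)
            exp = refit_signatures(cat, reference, sparsity_tol=None)
            b = cat.to_numpy()
            w = np.zeros(5)
            step = 1.0 / np.linalg.norm(a.T @ a, 2)
            for _ in range(2000):
                w = np.maximum(0.0, w - step * (a.T @ (a @ w - b)))
            oracle_resid = np.linalg.norm(a @ w - b)
            assert exp.reconstruction_error <= oracle_resid + 1e-6

    def test_dimension_mismatch(self, reference):
        with pytest.raises(ValueError):
            refit_signatures(pd.Series([1.0, 2.0], index=["x", "y"]), reference)


# ---------------------------------------------------------------------------
# neoantigen filter
# ---------------------------------------------------------------------------

class TestNeoantigenFilter:
    def table(self):
        return pd.DataFrame(
            {
                "peptide": ["kept", "at_affinity_cut", "at_expr_cut", "strong", "missing"],
                "affinity_nm": [499.0, 500.0, 10.0, 20.0, np.nan],
                "expression": [1.5, 5.0, 1.0, 8.0, 9.0],
            }
        )

    def test_strict_cutoffs(self):
        with pytest.warns(UserWarning, match="missing"):
            kept = filter_neoantigens(self.table())
        assert list(kept["peptide"]) == ["kept", "strong"]

    def test_configurable_cuts(self):
        kept = filter_neoantigens(self.table().dropna(), affinity_cut_nm=1000, expr_cut=0)
        assert len(kept) == 4
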