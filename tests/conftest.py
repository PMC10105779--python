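import numpy as np
import pandas as pd
import pytest

from calcomics import CohortSpec, generate_cohort, synthetic_build


@pytest.fixture(scope="session")
def build():
    return synthetic_build()


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient synthetic cohort shared across read-only tests."""
    return generate_cohort(CohortSpec(n_samples=60, seed=42))


@pytest.fixture(scope="session")
def groups(small_cohort):
    return small_cohort.cohort.set_index("sample")["group"]


def make_segments(rows, sample="S1"):
    """Segment DataFrame from (chrom, start, end, nMajor, nMinor) tuples."""
    return pd.DataFrame(
        [(sample, c, s, e, a, b) for c, s, e, a, b in rows],
        columns=["sample", "chromosome", "start", "end", "nMajor", "nMinor"],
    )


def make_mutations(rows):
    """Mutation DataFrame from (sample, chrom, pos, ref, alt, vclass, ctx)."""
    return pd.DataFrame(
        [(s, "GENE0001", c, p, r, a, v, x) for s, c, p, r, a, v, x in rows],
        columns=[
            "Tumor_Sample_Barcode",
            "Hugo_Symbol",
            "Chromosome",
            "Start_Position",
            "Reference_Allele",
            "Tumor_Seq_Allele2",
            "Variant_Classification",
            "Trinucleotide_Context",
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
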