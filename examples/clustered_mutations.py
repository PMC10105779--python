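"""Clustered-mutation detection and SBS96 signature refitting.

A per-sample inter-mutational-distance (IMD) threshold is calibrated against
100 uniform background simulations; runs of mutations under the threshold are
classified as DBS / MBS / omikli / kataegis. The SBS96 catalog is then refit
against a toy reference signature set by non-negative least squares.
"""

import numpy as np
import pandas as pd

from calcomics import build_sbs96, classify_clustered_mutations, imd_threshold, refit_signatures
from calcomics.genome import synthetic_build
from calcomics.mutations import SBS96_CLASSES

build = synthetic_build()
rng = np.random.default_rng(0)

rows = [
    ("S1", "GENE0001", f"chr{rng.integers(1, 11)}", int(rng.integers(1, 10**8)), "C", "T",
     "Missense_Mutation", "ACA")
    for _ in range(60)
]
rows += [  # a planted kataegis focus on chr1
    ("S1", "GENE0002", "chr1", 5_000_000 + 250 * i, "C", "T", "Missense_Mutation", "TCA")
    for i in range(6)
]
muts = pd.DataFrame(rows, columns=[
    "Tumor_Sample_Barcode", "Hugo_Symbol", "Chromosome", "Start_Position",
    "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Classification", "Trinucleotide_Context",
])

res = imd_threshold(muts, build, seed=1)
print(f"IMD threshold: {res.threshold} bp ({res.n_simulations} simulations, q={res.q_value:.3f})")
calls = classify_clustered_mutations(muts, res.threshold)
print(calls["cluster_class"].value_counts().to_string())

catalog = build_sbs96(muts)
# toy reference: SBS_A is an ACA/TCA C>T process like the one simulated above,
# SBS_B and SBS_C are unrelated flat/random processes
sbs_a = pd.Series(0.0, index=list(SBS96_CLASSES))
sbs_a[["A[C>T]A", "T[C>T]A"]] = 0.5
reference = pd.DataFrame(
    [sbs_a, pd.Series(1 / 96, index=sbs_a.index),
     pd.Series(np.random.default_rng(1).dirichlet(np.ones(96)), index=sbs_a.index)],
    index=["SBS_A", "SBS_B", "SBS_C"],
)
exposure = refit_signatures(catalog, reference)
print("exposures:", exposure.exposures.round(1).to_dict(),
      f"cosine={exposure.cosine_similarity:.3f}")
# The 6 planted mutations come out as one kataegis focus; the 60 uniform
# background mutations stay non-clustered.
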