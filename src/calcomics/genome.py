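"""Genome builds: chromosome lengths, centromeres, and HLA class-I loci.

Coordinates are 1-based inclusive throughout the package, matching SEG/MAF
conventions. A small synthetic build (10 chromosomes x 100 Mb) ships with the
package so that simulations and tests never need a reference genome; real
builds can be loaded from a cytoband-style TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

MB = 1_000_000


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths and centromere intervals, 1-based inclusive.

    Parameters
    ----------
    chromosomes : dict mapping chromosome name -> length in bp.
    centromeres : dict mapping chromosome name -> (start, end) in bp, or empty
        to disable arm-aware logic.
    hla_loci : dict mapping locus name (HLA-A/B/C) -> (chromosome, start, end).
    """

    chromosomes: dict[str, int]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)
    hla_loci: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("GenomeBuild needs at least one chromosome")
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        for name, (cs, ce) in self.centromeres.items():
            if name not in self.chromosomes:
                raise ValueError(f"centromere for unknown chromosome {name!r}")
            if not (1 <= cs <= ce <= self.chromosomes[name]):
                raise ValueError(f"centromere interval ({cs}, {ce}) outside chromosome {name!r}")
        for locus, (chrom, start, end) in self.hla_loci.items():
            if chrom not in self.chromosomes:
                raise ValueError(f"HLA locus {locus!r} on unknown chromosome {chrom!r}")
            if not (1 <= start <= end <= self.chromosomes[chrom]):
                raise ValueError(f"HLA locus {locus!r} interval outside chromosome {chrom!r}")

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r} for this genome build") from None

    def arms(self, chrom: str) -> list[tuple[int, int]]:
        """Arm intervals of a chromosome: [p, q] if a centromere is defined,
        otherwise the whole chromosome as a single interval."""
        length = self.length(chrom)
        cen = self.centromeres.get(chrom)
        if cen is None:
            return [(1, length)]
        cs, ce = cen
        arms = []
        if cs > 1:
            arms.append((1, cs - 1))
        if ce < length:
            arms.append((ce + 1, length))
        return arms


def synthetic_build(n_chromosomes: int = 10, chrom_length: int = 100 * MB) -> GenomeBuild:
    """The package's built-in toy genome: `n_chromosomes` chromosomes of equal
    length with a centromere spanning the middle 4% and toy HLA class-I loci
    on chr6 (mimicking the 6p21 arrangement)."""
    cen_half = int(0.02 * chrom_length)
    mid = chrom_length // 2
    chroms = {f"chr{i}": chrom_length for i in range(1, n_chromosomes + 1)}
    cens = {c: (mid - cen_half + 1, mid + cen_half) for c in chroms}
    hla = {}
    if "chr6" in chroms:
        hla = {
            "HLA-A": ("chr6", 29_900_000, 29_950_000),
            "HLA-B": ("chr6", 31_200_000, 31_270_000),
            "HLA-C": ("chr6", 31_300_000, 31_360_000),
        }
    return GenomeBuild(chromosomes=chroms, centromeres=cens, hla_loci=hla)


def read_build(path) -> GenomeBuild:
    """Load a genome build from a TSV with columns: chromosome, length,
    centromere_start, centromere_end (centromere columns optional/NA)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chromosome", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genome build file missing columns: {sorted(missing)}")
    if df["chromosome"].duplicated().any():
        dups = df.loc[df["chromosome"].duplicated(), "chromosome"].tolist()
        raise ValueError(f"duplicate chromosome names: {dups}")
    chroms = dict(zip(df["chromosome"].astype(str), df["length"].astype(int)))
    cens: dict[str, tuple[int, int]] = {}
    if {"centromere_start", "centromere_end"} <= set(df.columns):
        for _, row in df.iterrows():
            if pd.notna(row["centromere_start"]) and pd.notna(row["centromere_end"]):
                cens[str(row["chromosome"])] = (
                    int(row["centromere_start"]),
                    int(row["centromere_end"]),
                )
    return GenomeBuild(chromosomes=chroms, centromeres=cens)


def write_build(build: GenomeBuild, path) -> None:
    rows = []
    for chrom, length in build.chromosomes.items():
        cs, ce = build.centromeres.get(chrom, (None, None))
        rows.append({"chromosome": chrom, "length": length, "centromere_start": cs, "centromere_end": ce})
    with open(path, "w") as fh:
        fh.write("# coordinates=1-based-inclusive\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
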