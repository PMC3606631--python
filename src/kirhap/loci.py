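"""Canonical KIR gene order, regions and hybrid pseudo-loci.

The KIR cluster on chromosome 19q13.4 is a tandem array of highly homologous
genes whose order along the chromosome is invariant; haplotypes differ in
which genes are present and in how many copies.  The region splits into a
centromeric and a telomeric half at the large 3DP1-2DL4 intergenic interval,
the major recombination hotspot.

Two bookkeeping conventions used throughout the package:

* 2DS3 and 2DS5 are distinct loci at the assay/genotype level but occupy the
  same structural slot (the ``2DS35`` block next to 2DL5); catalog haplotypes
  record the merged ``2DS35`` count.
* Unequal crossovers create hybrid (fusion) pseudo-loci carrying the 5'
  segment of one parent gene and the 3' segment of another.  Each hybrid has
  a segment boundary (the last exon belonging to the 5' parent) which decides
  which parent's diagnostic bases it presents in a given amplicon assay.
"""

from __future__ import annotations

from dataclasses import dataclass

#: The 16 KIR genes in canonical chromosomal order (2DL5/2DS35 can reside in
#: either half; they are listed at their centromeric slot).
CANONICAL_LOCI: tuple[str, ...] = (
    "3DL3", "2DS2", "2DL2", "2DL3", "2DL5", "2DS3", "2DS5",
    "2DP1", "2DL1", "3DP1", "2DL4", "3DL1", "3DS1", "2DS1", "2DS4", "3DL2",
)

#: Catalog-level loci: 2DS3 + 2DS5 collapsed into the 2DS35 block.
CATALOG_LOCI: tuple[str, ...] = (
    "3DL3", "2DS2", "2DL2", "2DL3", "2DL5", "2DS35",
    "2DP1", "2DL1", "3DP1", "2DL4", "3DL1", "3DS1", "2DS1", "2DS4", "3DL2",
)

#: Hybrid pseudo-loci: name -> (5' parent, 3' parent, boundary exon).  The
#: boundary exon is the last exon derived from the 5' parent: crossovers sit
#: in intron 3 for 2DL1/S1 and 2DP1/L1, intron 5/exon 6 for 3DL1/L2 and
#: intron 6 for 2DS2/S3.
HYBRID_LOCI: dict[str, tuple[str, str, int]] = {
    "2DL1/S1": ("2DL1", "2DS1", 3),
    "2DP1/L1": ("2DP1", "2DL1", 3),
    "3DL1/L2": ("3DL1", "3DL2", 5),
    "2DS2/S3": ("2DS2", "2DS3", 6),
}

#: Pseudo-locus for the ~15 kb partial 3DL2 deletion (intron 3 to beyond
#: exon 9) seen on most cA01|tB01-del7 chromosomes.  Only exons 1-3 remain,
#: so no exon>=4 assay detects it; modelled as a "hybrid" of 3DL2 with
#: nothing, boundary exon 3.
PARTIAL_3DL2 = "3DL2p"

ALL_LOCI: tuple[str, ...] = CATALOG_LOCI + tuple(HYBRID_LOCI) + (PARTIAL_3DL2,)

#: Framework genes present on (nearly) every haplotype.
FRAMEWORK_LOCI: tuple[str, ...] = ("3DL3", "2DL4", "3DL2")

_REGIONS = {
    "3DL3": "centromeric", "2DS2": "centromeric", "2DL2": "centromeric",
    "2DL3": "centromeric", "2DL5": "centromeric", "2DS3": "centromeric",
    "2DS5": "centromeric", "2DS35": "centromeric", "2DP1": "centromeric",
    "2DL1": "centromeric",
    "3DP1": "framework-boundary", "2DL4": "framework-boundary",
    "3DL1": "telomeric", "3DS1": "telomeric", "2DS1": "telomeric",
    "2DS4": "telomeric", "3DL2": "telomeric",
}


@dataclass(frozen=True)
class GeneLocus:
    """One KIR locus: canonical name, rank along the chromosome, region."""

    name: str
    rank: int
    region: str

    def __post_init__(self):
        if self.name not in ALL_LOCI:
            raise ValueError(f"unknown KIR locus {self.name!r}")


def gene_loci() -> list[GeneLocus]:
    """The 16 canonical loci as :class:`GeneLocus`, in chromosomal order."""
    return [GeneLocus(n, i, _REGIONS[n]) for i, n in enumerate(CANONICAL_LOCI)]


def collapse_2ds35(counts: dict[str, int]) -> dict[str, int]:
    """Merge 2DS3 and 2DS5 counts into the 2DS35 block count."""
    out = {k: v for k, v in counts.items() if k not in ("2DS3", "2DS5")}
    s35 = counts.get("2DS3", 0) + counts.get("2DS5", 0) + counts.get("2DS35", 0)
    if s35:
        out["2DS35"] = s35
    return out
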