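"""Resolution of diploid genotypes into phased catalog haplotype pairs.

A genotype (diploid copy-number vector) is matched against all unordered
pairs of catalog haplotypes whose summed, assay-observable gene content
reproduces it.  The assignment rules used by the genotyping strategy --
invariant gene order, placement of the mobile 2DL5-2DS35 block from its
flanking genes, complete segregation of mutually exclusive genes, and
block-LD consistency -- are applied as audits recorded in the resolution
trace.  Genotypes no catalog pair explains are handed to the novel-structure
search, which looks for a grammar-valid haplotype that complements a known
partner.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .assays import GenotypeCall, observable_projection
from .errors import AnalysisError
from .loci import collapse_2ds35
from .reference import (
    CatalogTable,
    CopyVector,
    HaplotypeRecord,
    grammar_haplotypes,
)

# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

@dataclass
class DiploidResolution:
    """The catalog haplotype pairs consistent with one genotype."""

    sample_id: str
    consistent_pairs: list[tuple[str, str]]
    status: str  # unambiguous | ambiguous | unresolved | excluded
    rule_trace: list[tuple[str, str]] = field(default_factory=list)
    chosen_pair: tuple[str, str] | None = None


@dataclass(frozen=True)
class NovelCandidate:
    """A predicted novel haplotype structure complementing a known partner."""

    known_partner: str
    residual_content: CopyVector
    grammar_edits: tuple[str, ...]
    edit_count: int
    reconstructed_name: str = ""


class NovelInference(list):
    """Ranked novel candidates plus diagnostics for rejected residuals."""

    def __init__(self, candidates=(), diagnostics=()):
        super().__init__(candidates)
        self.diagnostics = list(diagnostics)


# --------------------------------------------------------------------------
# Pair enumeration
# --------------------------------------------------------------------------

_PAIR_INDEX_CACHE: dict = {}


def _pair_index(catalog: CatalogTable) -> dict:
    """projection -> sorted list of unordered catalog name pairs."""
    key = id(catalog)
    if key in _PAIR_INDEX_CACHE:
        return _PAIR_INDEX_CACHE[key]
    index: dict = {}
    recs = catalog.records
    for i in range(len(recs)):
        ci = recs[i].content.as_dict()
        for j in range(i, len(recs)):
            cj = recs[j].content.as_dict()
            s = {k: ci.get(k, 0) + cj.get(k, 0) for k in set(ci) | set(cj)}
            proj = observable_projection(s)
            pair = tuple(sorted((recs[i].name, recs[j].name)))
            index.setdefault(proj, []).append(pair)
    for v in index.values():
        v.sort()
    _PAIR_INDEX_CACHE[key] = index
    return index


def _genotype_projections(genotype) -> list:
    """Observable projections of a genotype's candidate copy vectors."""
    if isinstance(genotype, GenotypeCall):
        vecs = genotype.candidate_vectors
    elif isinstance(genotype, CopyVector):
        vecs = [genotype]
    else:
        vecs = [CopyVector.from_dict(dict(genotype), level="diploid",
                                     collapse_2DS35=False)]
    return [observable_projection(v.as_dict()) for v in vecs]


def enumerate_pairs(genotype, catalog: CatalogTable) -> list[tuple[str, str]]:
    """All unordered catalog pairs whose diplotype content matches.

    Matching is in assay-observable coordinates (2DS35 collapsed, hybrids
    merged into the parent they mimic); when the genotype carries several
    observationally tied copy vectors, pairs matching any of them are
    returned.  The result is deterministic (lexicographic by name pair).
    """
    index = _pair_index(catalog)
    pairs = set()
    for proj in _genotype_projections(genotype):
        pairs.update(index.get(proj, []))
    return sorted(pairs)


# --------------------------------------------------------------------------
# Rule-based phasing audit
# --------------------------------------------------------------------------

#: gene pairs the genotyping rules treat as completely segregated: an
#: individual carrying both must have them on different haplotypes
_SEGREGATED = (("2DL3", "2DS2"), ("2DS1", "2DS4"))

#: strong-LD blocks used as a secondary consistency audit
_LD_BLOCKS = (
    ("2DS2", "2DL2"),
    ("2DP1", "2DL1"),
    ("3DP1", "2DL4"),
    ("3DL1", "2DS4"),
    ("3DS1", "2DS1"),
)


def _block_residence(rec: HaplotypeRecord) -> str | None:
    """Which side of the haplotype carries its 2DL5-2DS35 block(s)."""
    cen = rec.cen_motif in ("cB01", "cB03") and "del9" not in rec.submotifs \
        and "del10" not in rec.submotifs
    tel = rec.tel_motif == "tB01" and not any(
        s in ("del6", "del7", "del8") for s in rec.submotifs)
    if "ins5" in rec.submotifs:
        tel = True
    if cen and tel:
        return "both"
    if cen:
        return "centromeric"
    if tel:
        return "telomeric"
    return None


def phase_with_rules(pairs, genotype, catalog: CatalogTable,
                     sample_id=None) -> DiploidResolution:
    """Audit enumerated pairs with the haplotype assignment rules.

    Applies the segregation rule (mutually exclusive genes on different
    haplotypes), the 2DL5-2DS35 placement rule (residence read off the
    flanking 2DP1-2DL1 / 3DS1-2DS1 copies) and the block-LD audit; every
    applied rule leaves a trace entry, and a pair failing a hard rule is
    removed with a trace entry, never silently.
    """
    if sample_id is None:
        sample_id = getattr(genotype, "sample_id", "sample")
    trace: list[tuple[str, str]] = []

    if isinstance(genotype, GenotypeCall):
        gvec = genotype.copies.as_dict()
        if genotype.provisional_loci:
            trace.append((
                "presence",
                "excluded: provisional presence (single confirmation) for "
                + ",".join(genotype.provisional_loci),
            ))
            return DiploidResolution(sample_id, [], "excluded", trace)
    else:
        gvec = dict(genotype.as_dict() if isinstance(genotype, CopyVector)
                    else genotype)
    gvec = collapse_2ds35(gvec)

    surviving = []
    for pair in pairs:
        r1, r2 = catalog[pair[0]], catalog[pair[1]]
        ok = True
        # rule (i) is structural: gene order is invariant in the catalog
        for a, b in _SEGREGATED:
            if gvec.get(a, 0) and gvec.get(b, 0):
                c1, c2 = r1.content.as_dict(), r2.content.as_dict()
                if (c1.get(a, 0) and c1.get(b, 0)) or \
                        (c2.get(a, 0) and c2.get(b, 0)):
                    trace.append((
                        "rule-iii",
                        f"removed {pair}: {a} and {b} must segregate to "
                        "different haplotypes",
                    ))
                    ok = False
        if ok:
            surviving.append(pair)

    if gvec.get("2DL5", 0):
        sides = {
            tuple(sorted(filter(None, (_block_residence(catalog[p[0]]),
                                       _block_residence(catalog[p[1]])))))
            for p in surviving
        }
        trace.append((
            "rule-ii",
            "2DL5-2DS35 residence from flanking 2DP1-2DL1/3DS1-2DS1 copies: "
            + (" | ".join("+".join(s) for s in sorted(sides)) or "n/a"),
        ))
    for a, b in _LD_BLOCKS:
        if gvec.get(a, 0) != gvec.get(b, 0):
            trace.append((
                "rule-iv",
                f"block-LD audit: {a} ({gvec.get(a, 0)}) and {b} "
                f"({gvec.get(b, 0)}) copies differ (block altered)",
            ))

    if not surviving:
        status, chosen = "unresolved", None
    elif len(surviving) == 1:
        status, chosen = "unambiguous", surviving[0]
    else:
        status, chosen = "ambiguous", None
    return DiploidResolution(sample_id, surviving, status, trace, chosen)


def resolve_genotype(genotype, catalog: CatalogTable) -> DiploidResolution:
    """enumerate_pairs + phase_with_rules in one call."""
    pairs = enumerate_pairs(genotype, catalog)
    return phase_with_rules(pairs, genotype, catalog)


# --------------------------------------------------------------------------
# Novel-haplotype inference
# --------------------------------------------------------------------------

def _normalized_submotifs(rec: HaplotypeRecord) -> tuple[str, frozenset]:
    """(cen base, edit set) with cB03 counted as one insert edit on cA01."""
    cen, edits = rec.cen_motif, set(rec.submotifs)
    if cen == "cB03":
        cen = "cA01"
        edits.add("cB03")
    if rec.partial_3DL2:
        edits.add("3DL2p")
    return cen, frozenset(edits)


def _edit_distance(g: HaplotypeRecord, catalog: CatalogTable) -> tuple[int, tuple]:
    """Minimal submotif-edit distance from ``g`` to any catalog haplotype."""
    gc, ge = _normalized_submotifs(g)
    best, ops = None, ()
    for h in catalog:
        hc, he = _normalized_submotifs(h)
        if (gc, g.tel_motif) != (hc, h.tel_motif):
            continue
        diff = tuple(sorted(ge ^ he))
        if best is None or len(diff) < best:
            best, ops = len(diff), diff
    if best is None:
        # no catalog haplotype shares the motif frame; count the frame
        # change plus every submotif as edits
        best, ops = 1 + len(ge), tuple(sorted(ge)) + ("motif-frame",)
    return best, ops


def infer_novel(genotype, catalog: CatalogTable,
                max_edits: int = 2) -> NovelInference:
    """Propose grammar-valid novel haplotypes for an unexplained genotype.

    For every catalog haplotype whose content fits under the genotype, the
    residual is matched against the full grammar universe (framework
    conservation, rule (v) and block contiguity are enforced by the grammar
    itself); candidates are ranked by edit count from the nearest catalog
    haplotype, then partner name.  Requires that ``enumerate_pairs`` found
    nothing.
    """
    if enumerate_pairs(genotype, catalog):
        raise AnalysisError(
            "genotype is explained by catalog pairs; novel inference "
            "refused (resolve it instead)"
        )
    universe = grammar_haplotypes(max_submotifs=max_edits)
    by_content: dict = {}
    for g in universe:
        key = tuple(sorted(collapse_2ds35(g.content.as_dict()).items()))
        by_content.setdefault(key, []).append(g)

    gvecs = []
    if isinstance(genotype, GenotypeCall):
        gvecs = [collapse_2ds35(v.as_dict()) for v in genotype.candidate_vectors]
    else:
        v = genotype.as_dict() if isinstance(genotype, CopyVector) else dict(genotype)
        gvecs = [collapse_2ds35(v)]

    candidates, diagnostics = [], []
    seen = set()
    for gvec in gvecs:
        for partner in catalog:
            pc = collapse_2ds35(partner.content.as_dict())
            residual = {k: gvec.get(k, 0) - pc.get(k, 0)
                        for k in set(gvec) | set(pc)}
            if any(c < 0 for c in residual.values()):
                continue
            residual = {k: c for k, c in residual.items() if c}
            key = tuple(sorted(residual.items()))
            if (partner.name, key) in seen:
                continue
            seen.add((partner.name, key))
            matches = by_content.get(key, [])
            if not matches:
                why = "no grammar-valid haplotype matches the residual"
                if residual.get("3DL3", 0) < 1 or (
                        residual.get("3DL2", 0) + residual.get("3DL1/L2", 0)
                        + residual.get("3DL2p", 0) < 1):
                    why = "residual violates framework conservation"
                diagnostics.append((partner.name, dict(residual), why))
                continue
            scored = sorted(
                (( *_edit_distance(g, catalog), g) for g in matches),
                key=lambda t: (t[0], t[2].name),
            )
            dist, ops, g = scored[0]
            if dist > max_edits:
                diagnostics.append((
                    partner.name, dict(residual),
                    f"nearest grammar haplotype {g.name} is {dist} edits away",
                ))
                continue
            candidates.append(NovelCandidate(
                known_partner=partner.name,
                residual_content=CopyVector.from_dict(residual, "haploid"),
                grammar_edits=ops,
                edit_count=dist,
                reconstructed_name=g.name,
            ))
    candidates.sort(key=lambda c: (c.edit_count, c.known_partner,
                                   c.reconstructed_name))
    return NovelInference(candidates, diagnostics)
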