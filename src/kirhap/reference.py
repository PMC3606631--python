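"""Gene-content haplotype grammar and the packaged 37-haplotype catalog.

A KIR gene-content haplotype is described as a combination of one centromeric
motif (cA01, cB01, cB02, cB03) and one telomeric motif (tA01, tB01), possibly
altered by *submotifs*: recurrent block deletions (del3-del10), block
insertions/duplications (ins3-ins5) and gene hybridizations (hybd1).  Names
follow the ``cen|tel[-submotif...]`` convention, e.g. ``cB02|tB01-del6``.

The packaged catalog holds the 37 validated haplotypes with population
frequencies.  Loading the catalog re-derives every record's gene-content
vector from its name through the grammar and checks it against the stored
counts, so the fixture data and the grammar cannot drift apart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import GrammarError, ParseError
from .loci import (
    CATALOG_LOCI,
    HYBRID_LOCI,
    PARTIAL_3DL2,
    collapse_2ds35,
)

# --------------------------------------------------------------------------
# Motifs
# --------------------------------------------------------------------------

#: Ordered gene lists of the six motifs.  cB03 is cA01 with the 2DL5-2DS35
#: block inserted between 2DL3 and 2DP1; it is listed both as a motif (for
#: haplotype construction) and as a submotif category (for Table-style
#: frequency summaries).
MOTIFS: dict[str, tuple[str, ...]] = {
    "cA01": ("3DL3", "2DL3", "2DP1", "2DL1", "3DP1"),
    "cB01": ("3DL3", "2DS2", "2DL2", "2DL5", "2DS35", "2DP1", "2DL1", "3DP1"),
    "cB02": ("3DL3", "2DS2", "2DL2", "3DP1"),
    "cB03": ("3DL3", "2DL3", "2DL5", "2DS35", "2DP1", "2DL1", "3DP1"),
    "tA01": ("2DL4", "3DL1", "2DS4", "3DL2"),
    "tB01": ("2DL4", "3DS1", "2DL5", "2DS35", "2DS1", "3DL2"),
}

CEN_MOTIFS = ("cA01", "cB01", "cB02", "cB03")
TEL_MOTIFS = ("tA01", "tB01")

_ALL_CEN = frozenset(CEN_MOTIFS)
_ALL_TEL = frozenset(TEL_MOTIFS)


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    genes: tuple[str, ...]


def motif_definitions() -> dict[str, MotifDefinition]:
    return {n: MotifDefinition(n, g) for n, g in MOTIFS.items()}


# --------------------------------------------------------------------------
# Submotif rules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubmotifRule:
    """One recurrent structural alteration of a major motif.

    ``operation`` is ``delete-block``, ``insert-block`` or ``hybridize``.
    ``affected_genes`` is the contiguous gene block removed or inserted;
    ``created_hybrids`` lists fusion pseudo-loci the event creates.
    ``applicable_parents`` is a list of ``(cen-set, tel-set)`` patterns: the
    rule may be applied when the haplotype's (cen, tel) pair matches one of
    them (the "associated region" of the frequency table).
    """

    name: str
    operation: str
    affected_genes: tuple[str, ...]
    created_hybrids: tuple[str, ...]
    applicable_parents: tuple[tuple[frozenset, frozenset], ...]
    description: str = ""

    def applies_to(self, cen: str, tel: str) -> bool:
        return any(cen in cs and tel in ts for cs, ts in self.applicable_parents)


def _pat(cens, tels):
    return (frozenset(cens), frozenset(tels))


SUBMOTIF_RULES: dict[str, SubmotifRule] = {
    r.name: r
    for r in [
        SubmotifRule(
            "cB03", "insert-block", ("2DL5", "2DS35"), (),
            (_pat({"cA01"}, _ALL_TEL),),
            "2DL5-2DS35 insertion into cA01 (between 2DL3 and 2DP1)",
        ),
        SubmotifRule(
            "del3", "delete-block", ("2DS2",), (),
            (_pat({"cB01", "cB02"}, _ALL_TEL),),
            "2DS2 deletion",
        ),
        SubmotifRule(
            "del4", "delete-block", ("2DL2",), (),
            (_pat({"cB01"}, _ALL_TEL),),
            "2DL2 deletion",
        ),
        SubmotifRule(
            "del5", "delete-block", ("3DP1", "2DL4", "3DL1"), (),
            (_pat({"cA01", "cB01"}, {"tA01"}),),
            "3DP1-2DL4-3DL1 deletion",
        ),
        SubmotifRule(
            "del6", "delete-block", ("3DP1", "2DL4", "3DS1"), (),
            (_pat({"cA01", "cB02"}, {"tB01"}),),
            "3DP1-2DL4-3DS1 deletion",
        ),
        SubmotifRule(
            "del7", "delete-block",
            ("2DL1", "3DP1", "2DL4", "3DS1", "2DL5", "2DS35", "2DS1"),
            ("2DL1/S1",),
            (_pat({"cA01", "cB01"}, {"tB01"}),),
            "2DL1(partial)-3DP1-2DL4-3DS1-2DL5-2DS35-2DS1(partial) deletion "
            "creating the 2DL1/S1 hybrid",
        ),
        SubmotifRule(
            "del8", "delete-block",
            ("2DL1", "3DP1", "2DL4", "3DS1", "2DL5", "2DS35", "2DS1"),
            ("2DL1/S1",),
            (_pat({"cA01"}, {"tB01"}),),
            "same gene block as del7 with distinct breakpoints (below "
            "gene-content resolution)",
        ),
        SubmotifRule(
            "del9", "delete-block", ("2DL5", "2DS35", "2DP1"), (),
            (_pat({"cB01"}, _ALL_TEL),),
            "2DL5-2DS35-2DP1 deletion",
        ),
        SubmotifRule(
            "del10", "delete-block", ("2DL2", "2DL5", "2DS35"), ("2DS2/S3",),
            (_pat({"cB01"}, _ALL_TEL),),
            "2DL2-2DL5-2DS35 deletion creating the 2DS2/S3 hybrid (2DS2*005)",
        ),
        SubmotifRule(
            "hybd1", "hybridize", ("3DL1", "2DS4", "3DL2"), ("3DL1/L2",),
            (_pat(_ALL_CEN, {"tA01"}),),
            "3DL1-3DL2 hybridization with 2DS4 deletion",
        ),
        SubmotifRule(
            "ins3", "insert-block", ("3DP1", "2DL4", "3DL1"), (),
            (
                _pat({"cA01", "cB01", "cB02"}, {"tA01"}),
                _pat({"cA01", "cB01"}, {"tB01"}),
            ),
            "3DP1-2DL4-3DL1 insertion",
        ),
        SubmotifRule(
            "ins4", "insert-block", ("3DP1", "2DL4", "3DS1"), (),
            (
                _pat({"cA01", "cB01", "cB02"}, {"tA01"}),
                _pat({"cA01", "cB01"}, {"tB01"}),
            ),
            "3DP1-2DL4-3DS1 insertion (3DL1 and 3DS1 in phase)",
        ),
        SubmotifRule(
            "ins5", "insert-block",
            ("3DP1", "2DL4", "3DS1", "2DL5", "2DS35"), ("2DP1/L1",),
            (
                _pat({"cA01", "cB01", "cB02", "cB03"}, {"tA01"}),
                _pat({"cB01"}, {"tB01"}),
            ),
            "3DP1-2DL4-3DS1-2DL5-2DS35-2DS1(partial) insertion with a "
            "secondary 2DP1 gene conversion creating the 2DP1/L1 hybrid",
        ),
    ]
}

#: Variant tags are name suffixes that change an attribute but not the
#: presence-level grammar: ``3DL2p`` marks the partial 3DL2 deletion carried
#: by most del7 chromosomes.
VARIANT_TAGS = ("3DL2p",)


# --------------------------------------------------------------------------
# Haplotype construction
# --------------------------------------------------------------------------

def _apply_rule(genes: list[str], rule: SubmotifRule) -> list[str]:
    """Apply one submotif rule to an ordered gene list (in place surgery)."""
    if rule.name == "cB03":
        i = genes.index("2DL3")
        return genes[: i + 1] + ["2DL5", "2DS35"] + genes[i + 1:]
    if rule.name in ("del3", "del4"):
        out = list(genes)
        out.remove(rule.affected_genes[0])
        return out
    if rule.name in ("del5", "del6", "del9"):
        return _remove_block(genes, list(rule.affected_genes), rule.name)
    if rule.name == "del10":
        out = _remove_block(genes, ["2DL2", "2DL5", "2DS35"], rule.name)
        out[out.index("2DS2")] = "2DS2/S3"
        return out
    if rule.name in ("del7", "del8"):
        out = _remove_block(genes, list(rule.affected_genes), rule.name)
        # the hybrid sits where 2DL1 was: just before the deleted block
        i = out.index("2DP1") + 1 if "2DP1" in out else out.index("3DL3") + 1
        return out[:i] + ["2DL1/S1"] + out[i:]
    if rule.name == "hybd1":
        out = _remove_block(genes, ["3DL1", "2DS4", "3DL2"], rule.name)
        return out + ["3DL1/L2"]
    if rule.name in ("ins3", "ins4"):
        # duplication in the telomeric half: insert after the first
        # 3DL1/3DS1 following the first 2DL4
        try:
            start = genes.index("2DL4")
        except ValueError:
            raise GrammarError(f"{rule.name}: no 2DL4 anchor left in haplotype")
        for j in range(start, len(genes)):
            if genes[j] in ("3DL1", "3DS1"):
                return genes[: j + 1] + list(rule.affected_genes) + genes[j + 1:]
        raise GrammarError(f"{rule.name}: no 3DL1/3DS1 anchor in {genes}")
    if rule.name == "ins5":
        # inserted block (with the 2DP1/L1 hybrid at its distal end) sits
        # between 2DL1 and the centromere-terminal 3DP1
        i = genes.index("3DP1")
        block = list(rule.affected_genes) + ["2DP1/L1"]
        return genes[:i] + block + genes[i:]
    raise GrammarError(f"unknown submotif rule {rule.name}")


def _remove_block(genes: list[str], block: list[str], rule_name: str) -> list[str]:
    """Remove a contiguous block; raises if the block is not contiguous."""
    n = len(block)
    for i in range(len(genes) - n + 1):
        if genes[i: i + n] == block:
            return genes[:i] + genes[i + n:]
    raise GrammarError(
        f"{rule_name}: block {'-'.join(block)} is not a contiguous run of "
        f"{'-'.join(genes)}"
    )


def haplotype_genes(cen: str, tel: str, submotifs: list[str] | tuple = ()) -> list[str]:
    """Ordered gene list of a haplotype built from motifs + submotif rules."""
    if cen not in CEN_MOTIFS or tel not in TEL_MOTIFS:
        raise GrammarError(f"unknown motif combination {cen}|{tel}")
    genes = list(MOTIFS[cen]) + list(MOTIFS[tel])
    for name in submotifs:
        rule = SUBMOTIF_RULES.get(name)
        if rule is None:
            raise GrammarError(f"unknown submotif rule {name!r}")
        if not rule.applies_to(cen, tel):
            raise GrammarError(
                f"submotif {name} is not applicable to {cen}|{tel} "
                f"(associated regions: {_fmt_parents(rule)})"
            )
        try:
            genes = _apply_rule(genes, rule)
        except ValueError as exc:
            raise GrammarError(
                f"submotif {name} cannot be applied to the remaining gene "
                f"list {genes}: {exc}"
            ) from exc
    return genes


def _fmt_parents(rule: SubmotifRule) -> str:
    return "; ".join(
        f"({'/'.join(sorted(cs))})|({'/'.join(sorted(ts))})"
        for cs, ts in rule.applicable_parents
    )


# --------------------------------------------------------------------------
# Copy vectors and records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CopyVector:
    """Per-locus copy counts at haploid or diploid level.

    ``counts`` maps locus name (catalog loci, hybrids, or 2DS3/2DS5 when not
    collapsed) to a non-negative integer.  Zero counts are omitted.
    """

    counts: tuple[tuple[str, int], ...]
    level: str = "haploid"  # haploid | diploid
    collapse_2DS35: bool = True

    @classmethod
    def from_dict(cls, counts: dict[str, int], level="haploid",
                  collapse_2DS35=True) -> "CopyVector":
        if collapse_2DS35:
            counts = collapse_2ds35(counts)
        items = tuple(sorted((k, int(v)) for k, v in counts.items() if v))
        return cls(items, level, collapse_2DS35)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def get(self, locus: str) -> int:
        return dict(self.counts).get(locus, 0)

    def __add__(self, other: "CopyVector") -> "CopyVector":
        a, b = self.as_dict(), other.as_dict()
        out = {k: a.get(k, 0) + b.get(k, 0) for k in set(a) | set(b)}
        return CopyVector.from_dict(
            out, "diploid", self.collapse_2DS35 and other.collapse_2DS35
        )

    def validate_haploid(self) -> None:
        """Check per-haplotype copy bounds and framework conservation."""
        d = self.as_dict()
        for locus, c in d.items():
            if c > 2:
                raise GrammarError(f"haploid count {locus}={c} exceeds 2")
        if d.get("3DL3", 0) < 1:
            raise GrammarError("framework gene 3DL3 missing from haplotype")
        # the 3DL1/L2 fusion carries the 3DL2-derived 3' tail; the del7
        # partial deletion retains 3DL2 exons 1-3
        if d.get("3DL2", 0) + d.get("3DL1/L2", 0) + d.get(PARTIAL_3DL2, 0) < 1:
            raise GrammarError("framework gene 3DL2 missing from haplotype")


def content_from_genes(genes: list[str], partial_3DL2: bool = False) -> CopyVector:
    counts: dict[str, int] = {}
    for g in genes:
        counts[g] = counts.get(g, 0) + 1
    if partial_3DL2:
        if counts.get("3DL2", 0) != 1:
            raise GrammarError("3DL2p tag requires exactly one 3DL2 copy")
        del counts["3DL2"]
        counts[PARTIAL_3DL2] = 1
    return CopyVector.from_dict(counts, "haploid")


@dataclass(frozen=True)
class HaplotypeRecord:
    """A named gene-content haplotype from the catalog."""

    name: str
    cen_motif: str
    tel_motif: str
    submotifs: tuple[str, ...]
    content: CopyVector
    frequency: float = 0.0
    partial_3DL2: bool = False

    @property
    def observable(self) -> dict[str, int]:
        """Content projected onto assay-observable coordinates.

        Hybrids that are observationally identical to a parent gene are
        merged into it (3DL1/L2 -> 3DL1, 2DL1/S1 -> 2DS1); the 3DL2 partial
        gene, invisible to every scored assay, is dropped.  2DP1/L1 and
        2DS2/S3 have assay-dependent behaviour and stay separate.
        """
        d = self.content.as_dict()
        out: dict[str, int] = {}
        for k, v in d.items():
            if k == PARTIAL_3DL2:
                continue
            if k == "3DL1/L2":
                k = "3DL1"
            elif k == "2DL1/S1":
                k = "2DS1"
            out[k] = out.get(k, 0) + v
        return out


def parse_name(name: str) -> tuple[str, str, tuple[str, ...], bool]:
    """Parse ``cen|tel[-submotif...][-3DL2p]`` into its components."""
    try:
        cen, rest = name.split("|", 1)
    except ValueError:
        raise ParseError(f"haplotype name {name!r} lacks the cen|tel separator")
    parts = rest.split("-")
    tel, tokens = parts[0], parts[1:]
    partial = "3DL2p" in tokens
    submotifs = tuple(t for t in tokens if t not in VARIANT_TAGS)
    if cen not in CEN_MOTIFS or tel not in TEL_MOTIFS:
        raise ParseError(f"haplotype name {name!r}: unknown motif {cen}|{tel}")
    return cen, tel, submotifs, partial


def build_haplotype(cen: str, tel: str, submotifs: list[str] | tuple = (),
                    frequency: float = 0.0, partial_3DL2: bool = False,
                    name: str | None = None) -> HaplotypeRecord:
    """Build a validated haplotype record from motifs and submotif rules."""
    genes = haplotype_genes(cen, tel, submotifs)
    content = content_from_genes(genes, partial_3DL2)
    content.validate_haploid()
    if name is None:
        name = f"{cen}|{tel}" + "".join(f"-{s}" for s in submotifs)
        if partial_3DL2:
            name += "-3DL2p"
    return HaplotypeRecord(
        name=name, cen_motif=cen, tel_motif=tel, submotifs=tuple(submotifs),
        content=content, frequency=frequency, partial_3DL2=partial_3DL2,
    )


def diplotype_vector(h1: HaplotypeRecord, h2: HaplotypeRecord) -> CopyVector:
    """Component-wise diploid sum of two haplotype contents (commutative)."""
    return h1.content + h2.content


# --------------------------------------------------------------------------
# Catalog
# --------------------------------------------------------------------------

@dataclass
class CatalogTable:
    """The validated haplotype catalog with population frequencies."""

    records: list[HaplotypeRecord]
    provenance: str = ""
    _by_name: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._by_name = {r.name: r for r in self.records}

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, name: str) -> HaplotypeRecord:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def frequencies(self) -> dict[str, float]:
        return {r.name: r.frequency for r in self.records}

    def validate(self) -> None:
        names = [r.name for r in self.records]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise GrammarError(f"duplicate haplotype name(s): {sorted(dupes)}")
        for rec in self.records:
            rebuilt = build_haplotype(
                rec.cen_motif, rec.tel_motif, rec.submotifs,
                partial_3DL2=rec.partial_3DL2,
            )
            if rebuilt.content != rec.content:
                raise GrammarError(
                    f"record {rec.name}: stored content "
                    f"{rec.content.as_dict()} does not match grammar "
                    f"reconstruction {rebuilt.content.as_dict()}"
                )
            rec.content.validate_haploid()
            d = rec.content.as_dict()
            # rule (v): the 2DP1-2DL1 block joins 2DL3 or 2DL5-2DS35,
            # never 2DS2-2DL2 directly
            if (d.get("2DS2", 0) and d.get("2DP1", 0)
                    and not d.get("2DL3", 0) and not d.get("2DL5", 0)):
                raise GrammarError(
                    f"record {rec.name} connects 2DS2-2DL2 directly to 2DP1"
                )
        total = sum(r.frequency for r in self.records)
        if abs(total - 1.0) > 1e-9:
            raise GrammarError(f"catalog frequencies sum to {total!r}, not 1")

    def to_tsv(self, path) -> None:
        write_catalog_tsv(self, path)

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "name": r.name, "cen_motif": r.cen_motif,
                    "tel_motif": r.tel_motif, "submotifs": list(r.submotifs),
                    "partial_3DL2": r.partial_3DL2,
                    "content": r.content.as_dict(), "frequency": r.frequency,
                }
                for r in self.records
            ],
            indent=2,
        )


def grammar_haplotypes(max_submotifs: int = 2,
                       include_partial: bool = True) -> list[HaplotypeRecord]:
    """Every structurally valid haplotype reachable by the grammar.

    Enumerates all motif combinations with up to ``max_submotifs`` submotif
    rules (applied in a fixed order), discarding combinations that violate
    applicability, contiguity, copy bounds or framework conservation.  The
    3DL2 partial-deletion variant is generated for del7/del8 haplotypes.
    This is the structural universe the copy-number solver and the novel-
    haplotype search work in; the catalog is the observed subset of it.
    """
    import itertools as _it

    rule_names = [n for n in SUBMOTIF_RULES if n != "cB03"]
    out, seen = [], set()
    for cen in CEN_MOTIFS:
        for tel in TEL_MOTIFS:
            for k in range(max_submotifs + 1):
                for subs in _it.combinations(rule_names, k):
                    try:
                        rec = build_haplotype(cen, tel, subs)
                    except GrammarError:
                        continue
                    variants = [rec]
                    if include_partial and any(
                            s in ("del7", "del8") for s in subs):
                        try:
                            variants.append(
                                build_haplotype(cen, tel, subs,
                                                partial_3DL2=True))
                        except GrammarError:
                            pass
                    for v in variants:
                        if v.name not in seen:
                            seen.add(v.name)
                            out.append(v)
    return out


_CONTENT_COLS = list(CATALOG_LOCI) + list(HYBRID_LOCI) + [PARTIAL_3DL2]


def write_catalog_tsv(catalog: CatalogTable, path) -> None:
    lines = ["\t".join(
        ["name", "cen_motif", "tel_motif", "submotifs"] + _CONTENT_COLS
        + ["frequency"]
    )]
    for r in catalog.records:
        d = r.content.as_dict()
        row = [r.name, r.cen_motif, r.tel_motif, ",".join(r.submotifs) or "."]
        row += [str(d.get(c, 0)) for c in _CONTENT_COLS]
        row.append(repr(r.frequency))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def _default_catalog_path() -> Path:
    return Path(resources.files("kirhap") / "data" / "haplotype_catalog.tsv")


def load_catalog(source=None) -> CatalogTable:
    """Load and validate a haplotype catalog table.

    ``source`` is a path to a tab-separated catalog file; by default the
    packaged 37-haplotype table is used.  Every record's content vector is
    recomputed from its motif + submotif decomposition and must equal the
    stored counts.
    """
    path = Path(source) if source is not None else _default_catalog_path()
    try:
        text = path.read_text()
    except OSError as exc:
        raise ParseError(f"cannot read catalog table {path}: {exc}") from exc
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    expected = ["name", "cen_motif", "tel_motif", "submotifs"] + _CONTENT_COLS + ["frequency"]
    if header != expected:
        raise ParseError(f"catalog header mismatch in {path}")
    records = []
    for ln in lines[1:]:
        f = ln.split("\t")
        if len(f) != len(expected):
            raise ParseError(f"catalog row has {len(f)} fields, expected {len(expected)}: {ln[:60]}")
        name, cen, tel, subs = f[0], f[1], f[2], f[3]
        submotifs = tuple(s for s in subs.split(",") if s and s != ".")
        counts = {c: int(v) for c, v in zip(_CONTENT_COLS, f[4:-1])}
        partial = counts.get(PARTIAL_3DL2, 0) > 0
        records.append(
            HaplotypeRecord(
                name=name, cen_motif=cen, tel_motif=tel, submotifs=submotifs,
                content=CopyVector.from_dict(counts, "haploid"),
                frequency=float(f[-1]), partial_3DL2=partial,
            )
        )
    catalog = CatalogTable(records, provenance=f"loaded from {path}")
    catalog.validate()
    return catalog
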