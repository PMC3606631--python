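"""The 14 amplicon assays: peak forward model, ratio classification and
copy-number integration.

Each assay is a multi-locus PCR amplicon sequenced with dye terminators.  At
scored SNP positions the relative peak height of a base is proportional to
the summed copy number of the amplified loci carrying that base, so integer
copy-number ratios can be read off the peak ratios.  Presence of a locus
requires at least two independent diagnostic targets; copy numbers are the
unique solution of all classified ratios, presence calls and the haplotype
block-structure rules.

Hybrid (fusion) genes present the diagnostic bases of whichever parent
contributes the segment containing the assay's exon, which is what lets the
assays distinguish, say, a 2DS2/S3 hybrid (2DS2-like in exon 4/5 assays,
2DS35-like in the exon 7/8 assay) from a plain 2DS2.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import CoverageError, NoSignalError, ParseError, UnresolvableGenotypeError
from .loci import HYBRID_LOCI, PARTIAL_3DL2
from .reference import CopyVector

#: A base is called present when its height is at least this fraction of the
#: tallest peak at the position.
DEFAULT_DETECTION_FLOOR = 0.05

#: Log-space tolerance for ratio classification: half the gap between
#: ln(3/2) and ln(1/1), the tightest adjacent pair of allowed classes.
DEFAULT_RATIO_TOLERANCE = 0.2

#: Loci exempt from the two-confirmation coverage requirement: 3DL3 carries
#: no assay target at all (framework gene, diploid count fixed at 2 by
#: assumption) and 2DL4/3DP1 are scored only jointly (C at position 170),
#: their individual counts being recovered through the block-structure rules.
COVERAGE_EXEMPT = frozenset({"3DL3", "2DL4", "3DP1"})


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpTarget:
    """One diagnostic SNP: a base at an amplicon position identifying a locus."""

    gene: str
    position: int
    base: str
    tier: str  # primary | secondary


@dataclass(frozen=True)
class RatioGroup:
    genes: tuple[str, ...]
    position: int
    base: str


@dataclass(frozen=True)
class RatioRule:
    """A copy-number rule: ordered gene groups with allowed integer classes.

    Most rules are pairwise (numerator/denominator); the 2DS1:2DL1:2DS4 rule
    is three-way.  ``open`` marks the 2DL5 rule whose printed class list is
    open-ended ("1 or multiple copies"): any small integer ratio is accepted
    and recorded verbatim.
    """

    groups: tuple[RatioGroup, ...]
    classes: tuple[tuple[int, ...], ...]
    open: bool = False

    @property
    def numerator_genes(self) -> tuple[str, ...]:
        return self.groups[0].genes

    @property
    def denominator_genes(self) -> tuple[str, ...]:
        return self.groups[-1].genes

    def candidate_classes(self) -> tuple[tuple[int, ...], ...]:
        if not self.open:
            return self.classes
        seen, out = set(), []
        for n1 in range(1, 5):
            for n2 in range(1, 9):
                g = math.gcd(n1, n2)
                t = (n1 // g, n2 // g)
                if t not in seen:
                    seen.add(t)
                    out.append(t)
        return tuple(out)


@dataclass(frozen=True)
class AssayDefinition:
    name: str
    exon: int
    genes_amplified: tuple[str, ...]
    incidental: tuple[str, ...]
    positions: dict  # position -> {base: (genes,)}
    snp_targets: tuple[SnpTarget, ...]
    ratio_rules: tuple[RatioRule, ...]

    def carriers(self, position: int, base: str) -> tuple[str, ...]:
        return self.positions.get(position, {}).get(base, ())


@dataclass(frozen=True)
class PeakObservation:
    """Relative fluorescence heights per base at one assay position."""

    sample_id: str
    assay_name: str
    position: int
    heights: tuple[tuple[str, float], ...]

    @classmethod
    def make(cls, sample_id, assay_name, position, heights: dict) -> "PeakObservation":
        return cls(sample_id, assay_name, position,
                   tuple(sorted(heights.items())))

    def height(self, base: str) -> float:
        return dict(self.heights).get(base, 0.0)

    def as_dict(self) -> dict[str, float]:
        return dict(self.heights)


@dataclass(frozen=True)
class RatioClassification:
    """Outcome of classifying observed peak heights against a ratio rule.

    ``kind`` is ``class`` (an allowed integer class was matched), ``absent``
    (the pattern of detectable groups matches no allowed class, e.g. an
    absent denominator) or ``unclassifiable`` (all groups detectable but no
    class within tolerance).
    """

    kind: str
    present: tuple[bool, ...]
    ratio_class: tuple[int, ...] | None = None
    # the log-space distance is diagnostic only; classifications are equal
    # when kind, presence pattern and class agree
    distance: float = field(default=0.0, compare=False)

    def __str__(self):
        if self.kind == "class":
            return ":".join(map(str, self.ratio_class))
        if self.kind == "absent":
            return "absent[" + "".join("+-"[not p] for p in self.present) + "]"
        return "unclassifiable"


@dataclass
class GenotypeCall:
    """Per-sample diploid copy-number vector with evidence bookkeeping.

    When several observationally indistinguishable copy vectors satisfy
    every constraint (the assays read relative ratios, so rare structural
    configurations can tie), ``copies`` holds the deterministic primary
    candidate and ``alternatives`` the others; downstream haplotype-pair
    matching weighs them against the catalog.
    """

    sample_id: str
    copies: CopyVector
    presence_evidence: dict[str, int] = field(default_factory=dict)
    discordances: list[tuple] = field(default_factory=list)
    quality: list[str] = field(default_factory=list)
    alternatives: list = field(default_factory=list)
    provisional_loci: list[str] = field(default_factory=list)

    @property
    def candidate_vectors(self) -> list:
        return [self.copies] + list(self.alternatives)

    @property
    def is_clean(self) -> bool:
        return not self.discordances and not self.provisional_loci


# --------------------------------------------------------------------------
# Loading
# --------------------------------------------------------------------------

def _default_assay_path() -> Path:
    return Path(resources.files("kirhap") / "data" / "assays.yaml")


def load_assay_definitions(source=None, check_coverage: bool = True):
    """Load the packaged (or a user) assay table and verify locus coverage.

    Every non-incidental locus must be identifiable through at least two
    diagnostic targets across the table (loci in :data:`COVERAGE_EXEMPT` are
    documented exceptions).  Returns the list of 14 assay definitions.
    """
    path = Path(source) if source is not None else _default_assay_path()
    try:
        raw = yaml.safe_load(path.read_text())
    except OSError as exc:
        raise ParseError(f"cannot read assay table {path}: {exc}") from exc
    assays = []
    for a in raw["assays"]:
        positions = {
            int(pos): {b: tuple(genes) for b, genes in bases.items()}
            for pos, bases in a["positions"].items()
        }
        targets = tuple(
            SnpTarget(t["gene"], int(t["position"]), t["base"], t["tier"])
            for t in a["targets"]
        )
        rules = tuple(
            RatioRule(
                groups=tuple(
                    RatioGroup(tuple(g["genes"]), int(g["position"]), g["base"])
                    for g in r["groups"]
                ),
                classes=tuple(tuple(c) for c in r.get("classes", [])),
                open=bool(r.get("open", False)),
            )
            for r in a.get("ratios", [])
        )
        assays.append(
            AssayDefinition(
                name=a["name"], exon=int(a["exon"]),
                genes_amplified=tuple(a["genes"]),
                incidental=tuple(a.get("incidental", [])),
                positions=positions, snp_targets=targets, ratio_rules=rules,
            )
        )
    if check_coverage:
        report = coverage_report(assays)
        short = {
            loc: n for loc, n in report.items()
            if n < 2 and loc not in COVERAGE_EXEMPT
        }
        if short:
            raise CoverageError(
                f"loci with fewer than 2 diagnostic confirmations: {short}"
            )
    return assays


def coverage_report(assays) -> dict[str, int]:
    """Diagnostic-target count per locus label (deterministic order)."""
    counts: dict[str, int] = {}
    loci = set()
    for a in assays:
        for g in a.genes_amplified:
            loci.add(g)
        for t in a.snp_targets:
            counts[t.gene] = counts.get(t.gene, 0) + 1
    # 2DS35 generic targets confirm the block, not 2DS3/2DS5 individually
    for locus in sorted(loci | {"3DL3"}):
        counts.setdefault(locus, 0)
    return dict(sorted(counts.items()))


# --------------------------------------------------------------------------
# Forward model
# --------------------------------------------------------------------------

def _hybrid_presents_as(hybrid: str, exon: int) -> str | None:
    if hybrid == PARTIAL_3DL2:
        return "3DL2" if exon <= 3 else None
    p5, p3, boundary = HYBRID_LOCI[hybrid]
    return p5 if exon <= boundary else p3


def effective_counts(diplotype: dict[str, int], assay: AssayDefinition) -> dict[str, int]:
    """Per-parent-gene copy counts as seen by one assay.

    Hybrid pseudo-loci are folded into the parent gene whose segment spans
    the assay's exon, provided that parent is amplified by the assay.
    """
    eff = {g: diplotype.get(g, 0) for g in assay.genes_amplified}
    for hyb in tuple(HYBRID_LOCI) + (PARTIAL_3DL2,):
        n = diplotype.get(hyb, 0)
        if not n:
            continue
        parent = _hybrid_presents_as(hyb, assay.exon)
        if parent in eff:
            eff[parent] += n
    return eff


def expected_peaks(diplotype, assay: AssayDefinition, gain: float = 1.0,
                   sample_id: str = "expected") -> list[PeakObservation]:
    """Noiseless peak heights of a diploid copy vector under one assay.

    Height of base *b* at position *p* is ``gain`` times the summed effective
    copy number of the amplified loci carrying *b* at *p*.
    """
    if isinstance(diplotype, CopyVector):
        diplotype = diplotype.as_dict()
    eff = effective_counts(diplotype, assay)
    out = []
    for pos in sorted(assay.positions):
        heights = {
            base: gain * float(sum(eff.get(g, 0) for g in genes))
            for base, genes in assay.positions[pos].items()
        }
        out.append(PeakObservation.make(sample_id, assay.name, pos, heights))
    return out


# --------------------------------------------------------------------------
# Ratio classification
# --------------------------------------------------------------------------

def classify_ratio(heights, rule: RatioRule,
                   tolerance: float = DEFAULT_RATIO_TOLERANCE,
                   detection_floor: float = DEFAULT_DETECTION_FLOOR,
                   present=None) -> RatioClassification:
    """Classify observed group heights against a rule's allowed classes.

    ``heights`` is one height per rule group (ordered as the rule's groups).
    A group counts as detectable when its height reaches ``detection_floor``
    of the largest group height (callers with full position context may pass
    ``present`` explicitly).  Among allowed classes whose zero pattern
    matches the detectable pattern, the class minimizing the largest pairwise
    log-ratio discrepancy is chosen; if that minimum exceeds ``tolerance``
    the observation is unclassifiable.
    """
    h = [float(x) for x in heights]
    if len(h) != len(rule.groups):
        raise ValueError("one height per rule group required")
    if present is None:
        top = max(h) if h else 0.0
        present = tuple(x > 0 and x >= detection_floor * top for x in h)
    else:
        present = tuple(bool(p) for p in present)
    if not any(present):
        raise NoSignalError(
            "no signal in any ratio group (every assay is expected to yield product)"
        )
    best, best_d = None, math.inf
    for cls in rule.candidate_classes():
        if tuple(n > 0 for n in cls) != present:
            continue
        idx = [i for i, p in enumerate(present) if p]
        d = 0.0
        for i, j in itertools.combinations(idx, 2):
            d = max(d, abs(math.log(h[i] / h[j]) - math.log(cls[i] / cls[j])))
        if d < best_d:
            best, best_d = cls, d
    if best is None:
        return RatioClassification("absent", present)
    if best_d > tolerance:
        return RatioClassification("unclassifiable", present, None, best_d)
    return RatioClassification("class", present, best, best_d)


# --------------------------------------------------------------------------
# Signatures
# --------------------------------------------------------------------------

def _position_presence(obs: PeakObservation, floor: float) -> frozenset:
    d = obs.as_dict()
    top = max(d.values(), default=0.0)
    if top <= 0:
        return frozenset()
    return frozenset(b for b, h in d.items() if h >= floor * top)


class AssaySignature:
    """Presence patterns and ratio classifications extracted from peaks.

    Two samples with the same signature are indistinguishable to the assay
    set; the copy-number solver searches for the unique copy vector whose
    predicted signature matches the observed one.  ``rule_heights`` keeps
    the raw group heights per ratio rule for continuous scoring of noisy
    data; it does not participate in signature identity.
    """

    def __init__(self, presence: dict, ratios: dict, rule_heights=None):
        self.presence = presence      # (assay, position) -> frozenset of bases
        self.ratios = ratios          # (assay, rule_index) -> RatioClassification
        self.rule_heights = rule_heights or {}

    def __eq__(self, other):
        return (self.presence, self.ratios) == (other.presence, other.ratios)

    def __hash__(self):
        return hash((tuple(sorted(self.presence.items())),
                     tuple(sorted(self.ratios.items()))))

    def key(self):
        return (tuple(sorted(self.presence.items())),
                tuple(sorted(self.ratios.items())))


def build_signature(observations, assays, floor=DEFAULT_DETECTION_FLOOR,
                    tolerance=DEFAULT_RATIO_TOLERANCE,
                    restrict=None) -> AssaySignature:
    """Signature of a set of peak observations (optionally restricted to a
    subset of assay names)."""
    by_assay: dict[str, dict[int, PeakObservation]] = {}
    for ob in observations:
        by_assay.setdefault(ob.assay_name, {})[ob.position] = ob
    presence, ratios, rule_heights = {}, {}, {}
    for a in assays:
        if restrict is not None and a.name not in restrict:
            continue
        pos_obs = by_assay.get(a.name, {})
        for pos in a.positions:
            ob = pos_obs.get(pos)
            presence[(a.name, pos)] = (
                _position_presence(ob, floor) if ob is not None else frozenset()
            )
        for ri, rule in enumerate(a.ratio_rules):
            hs, prs = [], []
            for g in rule.groups:
                ob = pos_obs.get(g.position)
                hs.append(ob.height(g.base) if ob is not None else 0.0)
                prs.append(
                    ob is not None and g.base in presence[(a.name, g.position)]
                )
            rule_heights[(a.name, ri)] = tuple(hs)
            if not any(prs):
                ratios[(a.name, ri)] = RatioClassification("absent", tuple(prs))
            else:
                ratios[(a.name, ri)] = classify_ratio(
                    hs, rule, tolerance=tolerance, present=prs
                )
    return AssaySignature(presence, ratios, rule_heights)


def predicted_signature(diplotype: dict, assays, restrict=None,
                        tolerance=DEFAULT_RATIO_TOLERANCE) -> AssaySignature:
    obs = []
    for a in assays:
        if restrict is not None and a.name not in restrict:
            continue
        obs.extend(expected_peaks(diplotype, a))
    return build_signature(obs, assays, restrict=restrict, tolerance=tolerance)


# --------------------------------------------------------------------------
# Observable projection (what the assay set can distinguish)
# --------------------------------------------------------------------------

def observable_projection(counts: dict[str, int]) -> tuple:
    """Project an extended copy vector onto assay-observable coordinates.

    Hybrids merge into the parent they mimic at the scored exons; two
    presence-only channels (2DP1-like signal in the exon-3 assay, 2DL1-like
    signal in the exon-3 amplicon) stay boolean.  Two copy vectors with equal
    projections produce identical assay signatures.
    """
    g = counts.get
    s35 = g("2DS3", 0) + g("2DS5", 0) + g("2DS35", 0)
    return (
        g("2DS2", 0) + g("2DS2/S3", 0),            # 2DS2-like, exon 4/5
        g("2DL2", 0),
        g("2DL3", 0),
        s35,                                        # 2DS35 block, exon 4
        s35 + g("2DS2/S3", 0),                      # 2DS35-like, exon 7/8
        g("2DL5", 0),
        g("2DP1", 0),                               # 2DP1-like, exon 4/5
        (g("2DP1", 0) + g("2DP1/L1", 0)) > 0,       # 2DP1-like, exon 3
        g("2DL1", 0) + g("2DP1/L1", 0),             # 2DL1-like, exon 4
        (g("2DL1", 0) + g("2DL1/S1", 0)) > 0,       # 2DL1-like, exon 3
        g("3DP1", 0),
        g("2DL4", 0),
        g("3DL1", 0) + g("3DL1/L2", 0),             # 3DL1-like, exon 4
        g("3DS1", 0),
        g("2DS1", 0) + g("2DL1/S1", 0),             # 2DS1-like, exon 4
        g("2DS4", 0),
        g("3DL2", 0),                               # full-gene 3DL2 only
    )


# --------------------------------------------------------------------------
# Copy-number integration
# --------------------------------------------------------------------------

class GenotypeSolver:
    """Copy-number solver over the grammar-valid diplotype universe.

    Every assay constraint (peak presence and peak ratio) is invariant to an
    overall scaling of the copy vector, so copy numbers are only identifiable
    jointly with the haplotype structure rule set: a diploid vector must be
    the sum of two grammar-valid haplotypes.  The solver therefore
    precomputes the assay signature of every unordered pair from the grammar
    universe (all structurally valid haplotypes, not just the catalog) and
    inverts signatures by lookup.  Where a 2DS35 block may be 2DS3 or 2DS5,
    every split is enumerated, since the assays distinguish them.
    """

    def __init__(self, assays, haplotypes=None,
                 floor=DEFAULT_DETECTION_FLOOR,
                 tolerance=DEFAULT_RATIO_TOLERANCE):
        from .reference import grammar_haplotypes

        self.assays = list(assays)
        self.floor = floor
        self.tolerance = tolerance
        self.haplotypes = list(haplotypes) if haplotypes is not None \
            else grammar_haplotypes()
        #: signature key -> {projection: counts}
        self._exact: dict = {}
        #: presence key -> list of (ratio dict, projection, counts)
        self._buckets: dict = {}
        self.n_candidates = 0
        self._build()

    @staticmethod
    def _splits(counts):
        """Concrete 2DS3/2DS5 assignments of the merged 2DS35 count."""
        m = counts.get("2DS35", 0)
        base = {k: v for k, v in counts.items() if k != "2DS35"}
        if not m:
            yield dict(base)
            return
        for s3 in range(m + 1):
            d = dict(base)
            if s3:
                d["2DS3"] = d.get("2DS3", 0) + s3
            if m - s3:
                d["2DS5"] = d.get("2DS5", 0) + (m - s3)
            yield d

    def _build(self):
        seen = set()
        haps = self.haplotypes
        for i in range(len(haps)):
            ci = haps[i].content.as_dict()
            for j in range(i, len(haps)):
                cj = haps[j].content.as_dict()
                merged = {k: ci.get(k, 0) + cj.get(k, 0)
                          for k in set(ci) | set(cj)}
                for counts in self._splits(merged):
                    key = tuple(sorted(counts.items()))
                    if key in seen:
                        continue
                    seen.add(key)
                    sig = predicted_signature(
                        counts, self.assays, tolerance=self.tolerance
                    )
                    proj = observable_projection(counts)
                    self._exact.setdefault(sig.key(), {})[proj] = counts
                    pres_key = tuple(sorted(sig.presence.items()))
                    self._buckets.setdefault(pres_key, []).append(
                        (sig.ratios, sig.rule_heights, proj, counts)
                    )
                    self.n_candidates += 1

    def solve_exact(self, observed: AssaySignature) -> dict:
        """All observationally distinct copy vectors matching the signature."""
        return dict(self._exact.get(observed.key(), {}))

    def solve_scored(self, observed: AssaySignature):
        """Best-scoring candidates when no exact signature match exists.

        Candidates sharing the observed presence pattern (presence calls
        are robust to multiplicative noise) are ranked by the summed
        squared log discrepancy between observed and expected peak ratios
        over all rules; presence-pattern mismatches within a rule carry a
        large fixed penalty.  Returns ``(candidates, mismatched_rule_keys)``
        where ``candidates`` maps the projections of the minimum-distance
        copy vectors (ties included) to counts.
        """
        pres_key = tuple(sorted(observed.presence.items()))
        bucket = [(0.0, cand) for cand in self._buckets.get(pres_key, [])]
        if not bucket:
            # corrupted/incomplete presence pattern: fall back to scoring
            # every candidate, penalizing presence disagreements
            obs_pres = observed.presence
            bucket = []
            for pk, cands in self._buckets.items():
                diff = sum(
                    1 for key, bases in pk
                    if obs_pres.get(key, frozenset()) != bases
                )
                for cand in cands:
                    bucket.append((1000.0 * diff, cand))
        best: dict = {}
        best_score, best_ratios = math.inf, None
        for base_penalty, (ratios, heights, proj, counts) in bucket:
            score = base_penalty
            for k, eh in heights.items():
                oh = observed.rule_heights.get(k)
                if oh is None:
                    continue
                e_pr = tuple(h > 0 for h in eh)
                obs_cls = observed.ratios.get(k)
                o_present = obs_cls.present if obs_cls is not None else tuple(
                    h > 0 for h in oh)
                if e_pr != o_present:
                    score += 100.0
                    continue
                idx = [i for i, p in enumerate(e_pr) if p]
                for x in range(len(idx)):
                    for y in range(x + 1, len(idx)):
                        i, j = idx[x], idx[y]
                        score += (math.log(oh[i] / oh[j])
                                  - math.log(eh[i] / eh[j])) ** 2
            if score < best_score - 1e-9:
                best = {proj: counts}
                best_score, best_ratios = score, ratios
            elif score <= best_score + 1e-9:
                best[proj] = counts
        mismatched = []
        if best_ratios is not None:
            mismatched = [
                k for k, v in best_ratios.items()
                if observed.ratios.get(k) != v
            ]
        return best, mismatched


_SOLVER_CACHE: dict = {}


def get_solver(assays, floor=DEFAULT_DETECTION_FLOOR,
               tolerance=DEFAULT_RATIO_TOLERANCE) -> GenotypeSolver:
    """Module-level solver cache (building the signature table is a one-time
    cost of a few seconds)."""
    key = (tuple(a.name for a in assays), floor, tolerance)
    if key not in _SOLVER_CACHE:
        _SOLVER_CACHE[key] = GenotypeSolver(assays, floor=floor,
                                            tolerance=tolerance)
    return _SOLVER_CACHE[key]


def _evidence(observed: AssaySignature, assays) -> dict[str, int]:
    ev: dict[str, int] = {}
    for a in assays:
        for t in a.snp_targets:
            if t.base in observed.presence.get((a.name, t.position), frozenset()):
                ev[t.gene] = ev.get(t.gene, 0) + 1
    return ev


def integrate_assays(observations, assays, sample_id=None,
                     floor=DEFAULT_DETECTION_FLOOR,
                     tolerance=DEFAULT_RATIO_TOLERANCE,
                     solver: GenotypeSolver | None = None) -> GenotypeCall:
    """Solve the diploid copy-number vector from all assay observations.

    The copy vector must agree with every classified ratio and presence
    call and be decomposable into two grammar-valid haplotypes.  With noisy
    or contradictory data no vector matches exactly; the solver then picks
    the vector minimizing the log-ratio discrepancy over all rules and
    records the discretely violated ones as discordances.  Observationally
    tied vectors are reported through ``alternatives``; an empty candidate
    set raises :class:`~kirhap.errors.UnresolvableGenotypeError`.
    """
    observations = list(observations)
    if sample_id is None:
        sample_id = observations[0].sample_id if observations else "sample"
    if solver is None:
        solver = get_solver(assays, floor=floor, tolerance=tolerance)
    seen_assays = {ob.assay_name for ob in observations}
    missing = [a.name for a in assays if a.name not in seen_assays]
    observed = build_signature(observations, assays, floor=floor,
                               tolerance=tolerance)

    quality, discordances = [], []
    exact_path = True
    if missing:
        quality.append("missing-assays:" + ",".join(sorted(missing)))

    solutions = solver.solve_exact(observed)
    if not solutions:
        exact_path = False
        best, mismatched = solver.solve_scored(observed)
        if not best:
            raise UnresolvableGenotypeError(
                f"{sample_id}: presence pattern matches no grammar-valid "
                "diplotype",
                constraints=sorted(str(v) for v in observed.ratios.values()),
            )
        solutions = best
        counts0 = next(iter(best.values()))
        by_assay = {a.name: a for a in assays}
        for a_name, ri in mismatched:
            rule = by_assay[a_name].ratio_rules[ri]
            genes = tuple(sorted({g for grp in rule.groups for g in grp.genes}))
            pred = predicted_signature(counts0, assays, restrict=(a_name,),
                                       tolerance=tolerance)
            discordances.append(
                (genes, a_name,
                 f"observed {observed.ratios.get((a_name, ri))} vs "
                 f"expected {pred.ratios.get((a_name, ri))}")
            )
        quality.append("ratio-discordance")

    ordered = [solutions[p] for p in sorted(solutions)]
    counts, alternatives = ordered[0], ordered[1:]
    if alternatives:
        quality.append(f"ambiguous-copy-number:{len(ordered)}")

    ev = _evidence(observed, assays)
    # a fully concordant solution explains every signal jointly (e.g. the
    # single 2DS35-side target of a 2DS2/S3 hybrid); singly-confirmed
    # presence is only provisional when the constraint system disagrees
    provisional = []
    if not exact_path:
        provisional = [
            loc for loc, n in sorted(ev.items())
            if 0 < n < 2 and loc not in COVERAGE_EXEMPT
        ]
        if provisional:
            quality.append("provisional:" + ",".join(provisional))

    return GenotypeCall(
        sample_id=sample_id,
        copies=CopyVector.from_dict(counts, level="diploid",
                                    collapse_2DS35=False),
        presence_evidence=ev,
        discordances=discordances,
        quality=quality,
        alternatives=[
            CopyVector.from_dict(c, level="diploid", collapse_2DS35=False)
            for c in alternatives
        ],
        provisional_loci=provisional,
    )
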