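"""Population genetics on gene-content haplotypes: EM frequency estimation,
motif-level summaries and pairwise linkage disequilibrium.

Diploid gene-content genotypes are unphased and often consistent with
several haplotype pairs (phase between the centromeric and telomeric half
cannot be read from copy numbers in double heterozygotes).  The standard
EM algorithm for multilocus haplotype frequencies handles this: a
genotype's likelihood is the sum of ``f(h1) f(h2)`` (times 2 for
heterozygous pairs) over its consistent pairs, and the E-step splits each
genotype's mass across pairs in proportion to the current frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError
from .reference import CatalogTable, HaplotypeRecord
from .resolve import DiploidResolution, enumerate_pairs

# --------------------------------------------------------------------------
# EM haplotype frequencies
# --------------------------------------------------------------------------

@dataclass
class FrequencyEstimate:
    frequencies: dict[str, float]
    loglik_trace: list[float]
    n_chromosomes: int
    converged: bool
    n_excluded: int = 0

    def __getitem__(self, name: str) -> float:
        return self.frequencies.get(name, 0.0)


def _pair_sets(genotypes, catalog):
    """Collapse a cohort to unique consistent-pair sets with counts."""
    groups: dict[tuple, int] = {}
    excluded = 0
    for g in genotypes:
        if isinstance(g, DiploidResolution):
            pairs = tuple(g.consistent_pairs)
            if g.status == "excluded":
                pairs = ()
        elif isinstance(g, (tuple, list)) and len(g) == 2 and all(
                isinstance(x, str) for x in g):
            pairs = (tuple(sorted(g)),)
        else:
            pairs = tuple(enumerate_pairs(g, catalog))
        if not pairs:
            excluded += 1
            continue
        groups[pairs] = groups.get(pairs, 0) + 1
    return groups, excluded


def em_frequencies(genotypes, catalog: CatalogTable, tol: float = 1e-8,
                   max_iter: int = 1000) -> FrequencyEstimate:
    """Maximum-likelihood haplotype frequencies from unphased genotypes.

    ``genotypes`` may contain :class:`~kirhap.assays.GenotypeCall` objects,
    :class:`~kirhap.resolve.DiploidResolution` objects or plain name pairs.
    Genotypes with no consistent catalog pair are excluded and counted.
    Initialization is uniform over the catalog; iteration stops when the
    log-likelihood improves by less than ``tol``.  The log-likelihood is
    non-decreasing at every step (a property of EM asserted in the tests).
    """
    names = catalog.names
    idx = {n: i for i, n in enumerate(names)}
    groups, excluded = _pair_sets(genotypes, catalog)
    if not groups:
        raise AnalysisError("no genotypes with at least one consistent pair")
    n_ind = sum(groups.values())

    # pair list per group as index arrays
    group_pairs = []
    weights = []
    for pairs, count in groups.items():
        i1 = np.array([idx[p[0]] for p in pairs])
        i2 = np.array([idx[p[1]] for p in pairs])
        mult = np.where(i1 == i2, 1.0, 2.0)
        group_pairs.append((i1, i2, mult))
        weights.append(float(count))
    weights = np.array(weights)

    f = np.full(len(names), 1.0 / len(names))
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        new = np.zeros_like(f)
        loglik = 0.0
        for (i1, i2, mult), w in zip(group_pairs, weights):
            lik = mult * f[i1] * f[i2]
            tot = lik.sum()
            if tot <= 0:
                # all consistent pairs have zero frequency; re-seed evenly
                lik = mult / mult.sum()
                tot = 1.0
                loglik += w * -math.inf
            else:
                loglik += w * math.log(tot)
                lik = lik / tot
            np.add.at(new, i1, w * lik)
            np.add.at(new, i2, w * lik)
        f = new / (2.0 * n_ind)
        trace.append(loglik)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    return FrequencyEstimate(
        frequencies={n: float(f[idx[n]]) for n in names},
        loglik_trace=trace,
        n_chromosomes=2 * n_ind,
        converged=converged,
        n_excluded=excluded,
    )


# --------------------------------------------------------------------------
# Motif summary
# --------------------------------------------------------------------------

_SUBMOTIF_ROWS = (
    "cB03", "del3", "del4", "del9", "del10", "hybd1", "del5", "del6",
    "del7/del8", "ins3", "ins4", "ins5",
)


@dataclass
class MotifSummary:
    """Frequency-table style aggregation of haplotype frequencies.

    Major rows count chromosomes whose centromeric (telomeric) motif is an
    unaltered cA01/cB01/cB02 (tA01/tB01); submotif rows aggregate
    single-alteration haplotypes (del7 and del8, which the assays cannot
    separate, are reported together); haplotypes carrying two or more
    alterations fall in the ``combined`` row.
    """

    cen: dict[str, float]
    tel: dict[str, float]
    submotifs: dict[str, float]
    combined: float
    n_chromosomes: int

    def submotif_total(self) -> float:
        return sum(self.submotifs.values()) + self.combined

    def as_rows(self):
        rows = [("centromere", k, v) for k, v in self.cen.items()]
        rows += [("telomere", k, v) for k, v in self.tel.items()]
        rows += [("submotif", k, v) for k, v in self.submotifs.items()]
        rows.append(("submotif", "combined", self.combined))
        return rows


def _category(rec: HaplotypeRecord) -> str | None:
    """Frequency-table row of one haplotype: None = unaltered major.

    A bare cB03 centromere is the cB03 insertion row; a cB03 haplotype
    with a submotif is filed under that submotif (the table lists cB03
    among the ins5 parents), and two or more submotifs are ``combined``.
    """
    subs = set(rec.submotifs)
    if not subs:
        return "cB03" if rec.cen_motif == "cB03" else None
    if len(subs) >= 2:
        return "combined"
    (s,) = subs
    return "del7/del8" if s in ("del7", "del8") else s


def motif_summary(estimate, catalog: CatalogTable) -> MotifSummary:
    """Aggregate haplotype frequencies into the motif/submotif table."""
    freqs = estimate.frequencies if isinstance(estimate, FrequencyEstimate) \
        else dict(estimate)
    n_chrom = getattr(estimate, "n_chromosomes", 0)
    cen = {k: 0.0 for k in ("cA01", "cB01", "cB02")}
    tel = {k: 0.0 for k in ("tA01", "tB01")}
    subs = {k: 0.0 for k in _SUBMOTIF_ROWS}
    combined = 0.0
    for rec in catalog:
        fr = freqs.get(rec.name, 0.0)
        cat_row = _category(rec)
        if cat_row is None:
            cen[rec.cen_motif] += fr
            tel[rec.tel_motif] += fr
        elif cat_row == "combined":
            combined += fr
        else:
            subs[cat_row] += fr
    return MotifSummary(cen=cen, tel=tel, submotifs=subs, combined=combined,
                        n_chromosomes=n_chrom)


def submotif_class_frequency(estimate, catalog: CatalogTable,
                             submotif: str) -> float:
    """Summed frequency of one submotif row of the frequency table.

    ``submotif`` may be a single rule name, ``"del7/del8"`` (the assays do
    not separate the two), ``"cB03"`` or ``"combined"``.  Row semantics
    match the table: a haplotype carrying two or more alterations counts in
    the ``combined`` row only.
    """
    freqs = estimate.frequencies if isinstance(estimate, FrequencyEstimate) \
        else dict(estimate)
    total = 0.0
    for rec in catalog:
        if _category(rec) == submotif:
            total += freqs.get(rec.name, 0.0)
    return total


# --------------------------------------------------------------------------
# Linkage disequilibrium
# --------------------------------------------------------------------------

@dataclass
class LdMatrix:
    genes: list[str]
    dprime: np.ndarray
    rsq: np.ndarray
    undefined: np.ndarray  # boolean mask; True where a gene is monomorphic

    def pair(self, a: str, b: str) -> tuple[float, float]:
        i, j = self.genes.index(a), self.genes.index(b)
        return float(self.dprime[i, j]), float(self.rsq[i, j])

    def is_defined(self, a: str, b: str) -> bool:
        i, j = self.genes.index(a), self.genes.index(b)
        return not (self.undefined[i] or self.undefined[j])


def ld_pairwise(haplotypes, frequencies=None, genes=None,
                weighted: bool = True) -> LdMatrix:
    """Pairwise D' and r-squared between gene presence/absence indicators.

    ``haplotypes`` is a catalog or list of haplotype records; by default
    each is weighted by its population frequency (``weighted=False`` treats
    the haplotype list as an unweighted sequence panel).  Presence means
    copy count >= 1; copy number is not used.  Genes present on every
    haplotype (or absent from all) are masked as undefined.
    """
    records = list(haplotypes)
    if len(records) < 2:
        raise AnalysisError("LD needs at least 2 haplotypes")
    if genes is None:
        loci = []
        for r in records:
            for k in r.content.as_dict():
                if "/" not in k and k not in loci and k != "3DL2p":
                    loci.append(k)
        genes = sorted(loci)
    if weighted:
        w = np.array([
            frequencies[r.name] if frequencies is not None else r.frequency
            for r in records
        ], dtype=float)
    else:
        w = np.ones(len(records))
    if w.sum() <= 0:
        raise AnalysisError("LD needs haplotypes with positive weight")
    w = w / w.sum()

    X = np.array([
        [1.0 if r.content.get(g) >= 1 else 0.0 for g in genes]
        for r in records
    ])
    p = w @ X
    n = len(genes)
    dprime = np.full((n, n), np.nan)
    rsq = np.full((n, n), np.nan)
    undefined = (p <= 1e-12) | (p >= 1.0 - 1e-12)
    for i in range(n):
        if undefined[i]:
            continue
        dprime[i, i] = 1.0
        rsq[i, i] = 1.0
        for j in range(i + 1, n):
            if undefined[j]:
                continue
            p11 = float(w @ (X[:, i] * X[:, j]))
            d = p11 - p[i] * p[j]
            if d >= 0:
                dmax = min(p[i] * (1 - p[j]), (1 - p[i]) * p[j])
            else:
                dmax = min(p[i] * p[j], (1 - p[i]) * (1 - p[j]))
            dp = 0.0 if dmax == 0 else d / dmax
            r2 = d * d / (p[i] * (1 - p[i]) * p[j] * (1 - p[j]))
            dprime[i, j] = dprime[j, i] = dp
            rsq[i, j] = rsq[j, i] = r2
    return LdMatrix(genes=list(genes), dprime=dprime, rsq=rsq,
                    undefined=undefined)
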