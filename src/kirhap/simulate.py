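"""Synthetic data generation: diploid cohorts, noisy peak observations and
aligned sequence triplets with planted recombination breakpoints.

The cohort simulator emulates a population survey genotyped with the
amplicon panel: haplotypes are drawn i.i.d. from the catalog frequencies
(Hardy-Weinberg pairing), each 2DS35 block is realized as 2DS3 or 2DS5,
and peak heights follow the assay forward model with a per-assay gain and
multiplicative lognormal noise (dye-terminator peak variability is
proportional to scale).  The triplet simulator plants crossovers between
two diverged parent sequences to exercise the breakpoint scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assays import PeakObservation, expected_peaks
from .errors import AnalysisError
from .reference import CatalogTable

#: Probability that a 2DS35 block carries 2DS3 rather than 2DS5.
DEFAULT_P_2DS3 = 0.5


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort and triplet generators."""

    n_individuals: int = 1000
    frequency_table: dict[str, float] | None = None  # default: catalog
    peak_noise_sigma: float = 0.1
    gain_range: tuple[float, float] = (0.5, 2.0)
    p_2DS3: float = DEFAULT_P_2DS3
    seed: int = 0
    # triplet parameters
    triplet_length: int = 5000
    divergence: float = 0.05
    breakpoints: tuple[int, ...] = (2500,)
    query_divergence: float = 0.0

    def __post_init__(self):
        if self.frequency_table is not None:
            tot = sum(self.frequency_table.values())
            if abs(tot - 1.0) > 1e-6:
                raise AnalysisError(
                    f"frequency table sums to {tot}, not 1")


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

def sample_cohort(config: SimulationConfig, catalog: CatalogTable):
    """Draw (sample_id, hap1, hap2) triples under Hardy-Weinberg pairing."""
    freqs = config.frequency_table or catalog.frequencies()
    unknown = [n for n in freqs if n not in catalog]
    if unknown:
        raise AnalysisError(f"frequency table names unknown haplotypes: {unknown}")
    names = sorted(freqs)
    p = np.array([freqs[n] for n in names], dtype=float)
    p = p / p.sum()
    rng = np.random.default_rng(config.seed)
    draws = rng.choice(len(names), size=(config.n_individuals, 2), p=p)
    return [
        (f"S{i:05d}", names[a], names[b])
        for i, (a, b) in enumerate(draws)
    ]


def realize_diplotype(hap1: str, hap2: str, catalog: CatalogTable,
                      rng=None, p_2DS3: float = DEFAULT_P_2DS3) -> dict:
    """Concrete diploid copy vector of a haplotype pair.

    Catalog records store the merged 2DS35 block; each block copy is
    realized as 2DS3 (probability ``p_2DS3``) or 2DS5, which is what the
    assays actually see.  With ``rng=None`` every block is 2DS3.
    """
    dip: dict[str, int] = {}
    for name in (hap1, hap2):
        for k, v in catalog[name].content.as_dict().items():
            dip[k] = dip.get(k, 0) + v
    m = dip.pop("2DS35", 0)
    for _ in range(m):
        if rng is not None and rng.random() >= p_2DS3:
            dip["2DS5"] = dip.get("2DS5", 0) + 1
        else:
            dip["2DS3"] = dip.get("2DS3", 0) + 1
    return dip


def simulate_peaks(pair, assays, config: SimulationConfig,
                   catalog: CatalogTable, rng=None,
                   sample_id: str = "sim") -> list[PeakObservation]:
    """Noisy peak observations for one haplotype pair.

    Heights are the forward-model expectation times a per-assay gain
    (uniform in ``gain_range``) times per-peak lognormal noise with
    ``peak_noise_sigma``; sigma 0 reproduces the exact forward model.
    Ratios within an assay are gain-invariant by construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dip = realize_diplotype(pair[0], pair[1], catalog, rng=rng,
                            p_2DS3=config.p_2DS3)
    sigma = config.peak_noise_sigma
    out = []
    for assay in assays:
        gain = rng.uniform(*config.gain_range)
        for ob in expected_peaks(dip, assay, gain=gain, sample_id=sample_id):
            if sigma > 0:
                noisy = {
                    b: h * float(np.exp(rng.normal(0.0, sigma))) if h > 0 else 0.0
                    for b, h in ob.as_dict().items()
                }
                ob = PeakObservation.make(sample_id, ob.assay_name,
                                          ob.position, noisy)
            out.append(ob)
    return out


# --------------------------------------------------------------------------
# Aligned triplets
# --------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass
class AlignedTriplet:
    """A recombinant query aligned with its two candidate parents."""

    query: str
    parent_a: str
    parent_b: str
    names: tuple[str, str, str] = ("query", "parentA", "parentB")
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.query) == len(self.parent_a) == len(self.parent_b)):
            raise AnalysisError("triplet sequences must be aligned (equal length)")

    @property
    def length(self) -> int:
        return len(self.query)


def simulate_triplet(config: SimulationConfig) -> AlignedTriplet:
    """Generate an aligned triplet with planted breakpoints.

    Parent A is i.i.d. uniform sequence; parent B differs at i.i.d.
    substitutions with rate ``divergence``.  The query copies parent A up
    to the first breakpoint, then alternates parents at each subsequent
    breakpoint; ``query_divergence`` adds private substitutions to the
    query (used for null triplets).  A truth record accompanies the output.
    """
    if not (0 <= config.divergence < 1):
        raise AnalysisError("divergence must be in [0, 1)")
    L = config.triplet_length
    for bp in config.breakpoints:
        if not (0 < bp < L):
            raise AnalysisError(f"breakpoint {bp} outside alignment (0, {L})")
    rng = np.random.default_rng(config.seed)
    a = rng.integers(0, 4, size=L)
    shift = rng.integers(1, 4, size=L)
    b = np.where(rng.random(L) < config.divergence, (a + shift) % 4, a)
    source = np.zeros(L, dtype=int)
    for bp in sorted(config.breakpoints):
        source[bp:] = 1 - source[bp]
    q = np.where(source == 0, a, b)
    if config.query_divergence > 0:
        shift_q = rng.integers(1, 4, size=L)
        q = np.where(rng.random(L) < config.query_divergence,
                     (q + shift_q) % 4, q)
    return AlignedTriplet(
        query="".join(_BASES[q]),
        parent_a="".join(_BASES[a]),
        parent_b="".join(_BASES[b]),
        truth={
            "breakpoints": sorted(int(x) for x in config.breakpoints),
            "divergence": config.divergence,
            "query_divergence": config.query_divergence,
            "seed": config.seed,
        },
    )
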