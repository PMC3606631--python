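"""EM haplotype frequencies, motif summaries, linkage disequilibrium."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kirhap.popgen import (
    em_frequencies,
    ld_pairwise,
    motif_summary,
    submotif_class_frequency,
)
from kirhap.reference import CatalogTable


# -- EM --------------------------------------------------------------------

def test_em_single_haplotype_cohort(catalog):
    cohort = [("cA01|tA01", "cA01|tA01")] * 100
    est = em_frequencies(cohort, catalog)
    assert est.frequencies["cA01|tA01"] == pytest.approx(1.0)
    assert est.n_chromosomes == 200


def test_em_equals_counting_on_unambiguous_cohort(catalog, rng):
    """When every genotype is a known unambiguous pair, the MLE is plain
    chromosome counting."""
    names = ["cA01|tA01", "cB01|tA01-del10", "cA01|tB01-del6"]
    cohort = []
    counts = {n: 0 for n in names}
    for _ in range(300):
        h1, h2 = rng.choice(names, size=2)
        cohort.append((h1, h2))
        counts[h1] += 1
        counts[h2] += 1
    est = em_frequencies(cohort, catalog)
    for n in names:
        assert est.frequencies[n] == pytest.approx(counts[n] / 600, abs=1e-9)


def test_em_loglik_monotone_and_simplex(catalog, assays):
    from kirhap.pipeline import run_pipeline
    result = run_pipeline(catalog, assays, 300, seed=11)
    trace = result.estimate.loglik_trace
    assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))
    f = np.array(list(result.estimate.frequencies.values()))
    assert (f >= -1e-12).all()
    assert f.sum() == pytest.approx(1.0, abs=1e-9)


def test_em_parameter_recovery_random_frequencies(catalog, assays):
    """Cohorts simulated at random frequency vectors are recovered within
    4 binomial SE for every haplotype (phase ambiguity resolved by EM)."""
    from kirhap.pipeline import run_pipeline
    rng = np.random.default_rng(5)
    names = catalog.names
    for trial in range(3):
        raw = rng.dirichlet(np.full(len(names), 0.4))
        freqs = {n: float(f) for n, f in zip(names, raw)}
        n = 2000
        result = run_pipeline(catalog, assays, n, seed=100 + trial,
                              frequency_table=freqs)
        # cA01|tB01-del7 and -del8 share one gene-content vector (the
        # assays cannot separate them); only their sum is identifiable
        classes = {}
        for name in names:
            key = name
            if name in ("cA01|tB01-del7", "cA01|tB01-del8"):
                key = "cA01|tB01-del7/8"
            classes.setdefault(key, []).append(name)
        for key, members in classes.items():
            p = sum(freqs[m] for m in members)
            est = sum(result.estimate.frequencies[m] for m in members)
            se = np.sqrt(max(p * (1 - p), 1e-12) / (2 * n))
            assert abs(est - p) <= max(4 * se, 0.01), (trial, key, p, est)


# -- motif summary ---------------------------------------------------------

def test_motif_summary_single_major(catalog):
    est = {"cA01|tA01": 1.0}
    ms = motif_summary(est, catalog)
    assert ms.cen["cA01"] == pytest.approx(1.0)
    assert ms.tel["tA01"] == pytest.approx(1.0)
    assert all(v == 0.0 for v in ms.submotifs.values())
    assert ms.combined == 0.0


def test_packaged_submotif_mass_rounds_to_seven_percent(catalog):
    """The packaged catalog's submotif-bearing haplotypes sum to ~7% of
    chromosomes."""
    ms = motif_summary(catalog.frequencies(), catalog)
    total = 100 * ms.submotif_total()
    assert round(total) == 7


def test_summary_additive_under_mass_split(catalog):
    """Aggregation only depends on total mass per haplotype class."""
    f1 = catalog.frequencies()
    ms1 = motif_summary(f1, catalog)
    # move mass between two haplotypes of the same submotif class
    f2 = dict(f1)
    delta = min(f2["cA01|tB01-del6"], 0.005)
    f2["cA01|tB01-del6"] -= delta
    f2["cB02|tB01-del6"] += delta
    ms2 = motif_summary(f2, catalog)
    assert ms2.submotifs["del6"] == pytest.approx(ms1.submotifs["del6"])


def test_submotif_class_frequencies_match_catalog_truth(catalog):
    f = catalog.frequencies()
    for row, pct in [("del6", 2.37), ("ins4", 1.01), ("hybd1", 0.39),
                     ("del7/del8", 0.61), ("del10", 0.19), ("cB03", 0.24),
                     ("combined", 0.16)]:
        assert 100 * submotif_class_frequency(f, catalog, row) == \
            pytest.approx(pct, abs=1e-6), row


# -- LD --------------------------------------------------------------------

def test_ld_exclusive_exhaustive_pair_is_perfect(catalog):
    """On the six major haplotypes 2DL3 and 2DS2 are mutually exclusive
    and jointly exhaustive: D' = 1 and r^2 = 1."""
    majors = CatalogTable(
        [r for r in catalog.records
         if not r.submotifs and r.cen_motif != "cB03"])
    ld = ld_pairwise(majors)
    dp, r2 = ld.pair("2DL3", "2DS2")
    assert abs(dp) == pytest.approx(1.0)
    assert r2 == pytest.approx(1.0)


def test_ld_monomorphic_framework_masked(catalog):
    ld = ld_pairwise(catalog)
    assert not ld.is_defined("3DL3", "2DL3")
    i = ld.genes.index("3DL3")
    assert ld.undefined[i]


def test_ld_bounds_random_weights(catalog, rng):
    """|D'| <= 1 and 0 <= r^2 <= 1 for random frequency vectors; diagonal
    r^2 is 1 for polymorphic genes."""
    names = catalog.names
    for _ in range(20):
        raw = rng.dirichlet(np.ones(len(names)))
        freqs = {n: float(f) for n, f in zip(names, raw)}
        ld = ld_pairwise(catalog, frequencies=freqs)
        finite_dp = ld.dprime[np.isfinite(ld.dprime)]
        finite_r2 = ld.rsq[np.isfinite(ld.rsq)]
        assert (np.abs(finite_dp) <= 1 + 1e-9).all()
        assert (finite_r2 <= 1 + 1e-9).all()
        assert (finite_r2 >= -1e-12).all()
        for i, g in enumerate(ld.genes):
            if not ld.undefined[i]:
                assert ld.rsq[i, i] == pytest.approx(1.0)


def test_ld_closed_form_equals_weighted_pearson(catalog, rng):
    """r^2 from the 2x2 table equals the squared weighted Pearson
    correlation of the presence indicators."""
    names = catalog.names
    for _ in range(20):
        raw = rng.dirichlet(np.ones(len(names)))
        freqs = {n: float(f) for n, f in zip(names, raw)}
        ld = ld_pairwise(catalog, frequencies=freqs)
        w = np.array([freqs[r.name] for r in catalog])
        w = w / w.sum()
        for a, b in [("2DL3", "2DS2"), ("2DL5", "2DS1"), ("3DL1", "2DS4")]:
            if not ld.is_defined(a, b):
                continue
            x = np.array([1.0 if r.content.get(a) else 0.0 for r in catalog])
            y = np.array([1.0 if r.content.get(b) else 0.0 for r in catalog])
            mx, my = w @ x, w @ y
            cov = w @ ((x - mx) * (y - my))
            vx = w @ ((x - mx) ** 2)
            vy = w @ ((y - my) ** 2)
            want = cov * cov / (vx * vy)
            assert ld.pair(a, b)[1] == pytest.approx(want, abs=1e-9)


def test_ld_unweighted_panel(catalog):
    ld = ld_pairwise(catalog, weighted=False)
    assert np.isfinite(ld.dprime[ld.genes.index("2DL3"),
                                 ld.genes.index("2DS2")])
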