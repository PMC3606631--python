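"""Diploid resolution against the catalog and novel-structure inference."""

import itertools

import numpy as np
import pytest

from conftest import diplotype_counts, noiseless_peaks
from kirhap.assays import integrate_assays, observable_projection
from kirhap.errors import AnalysisError
from kirhap.reference import CatalogTable, CopyVector, diplotype_vector
from kirhap.resolve import (
    enumerate_pairs,
    infer_novel,
    phase_with_rules,
    resolve_genotype,
)


def _vec(catalog, h1, h2):
    return CopyVector.from_dict(diplotype_counts(catalog, h1, h2),
                                level="diploid", collapse_2DS35=False)


def test_homozygote_enumerates_itself(catalog):
    pairs = enumerate_pairs(_vec(catalog, "cA01|tA01", "cA01|tA01"), catalog)
    assert ("cA01|tA01", "cA01|tA01") in pairs


def test_pairs_reproduce_genotype_vector(catalog):
    """Soundness: every returned pair sums to the query genotype in
    observable coordinates."""
    for h1, h2 in [("cA01|tA01", "cB02|tB01"), ("cB01|tB01", "cB01|tB01"),
                   ("cA01|tB01-del7", "cA01|tA01")]:
        vec = _vec(catalog, h1, h2)
        want = observable_projection(vec.as_dict())
        for p1, p2 in enumerate_pairs(vec, catalog):
            got = observable_projection(
                diplotype_vector(catalog[p1], catalog[p2]).as_dict())
            assert got == want


def test_segregated_genes_on_different_haplotypes(catalog):
    """An individual with both 2DL3 and 2DS2-2DL2 gets them assigned to
    different haplotypes in every returned pair."""
    vec = _vec(catalog, "cA01|tA01", "cB02|tB01")
    for p1, p2 in enumerate_pairs(vec, catalog):
        c1 = catalog[p1].content.as_dict()
        c2 = catalog[p2].content.as_dict()
        assert not (c1.get("2DL3") and c1.get("2DS2"))
        assert not (c2.get("2DL3") and c2.get("2DS2"))
        assert {bool(c1.get("2DL3")), bool(c2.get("2DL3"))} == {True, False} \
            or (c1.get("2DL3") and c2.get("2DL3"))


def test_completeness_against_brute_force(catalog, rng):
    """enumerate_pairs agrees with trying all |catalog|^2 ordered pairs on
    random genotypes built from random haplotype pairs."""
    names = catalog.names
    for _ in range(200):
        h1, h2 = rng.choice(names, size=2)
        vec = _vec(catalog, h1, h2)
        want = observable_projection(vec.as_dict())
        brute = set()
        for a, b in itertools.product(names, names):
            got = observable_projection(
                diplotype_vector(catalog[a], catalog[b]).as_dict())
            if got == want:
                brute.add(tuple(sorted((a, b))))
        assert set(enumerate_pairs(vec, catalog)) == brute


def test_determinism(catalog):
    vec = _vec(catalog, "cA01|tA01", "cB01|tB01")
    r1 = phase_with_rules(enumerate_pairs(vec, catalog), vec, catalog)
    r2 = phase_with_rules(enumerate_pairs(vec, catalog), vec, catalog)
    assert r1.consistent_pairs == r2.consistent_pairs
    assert r1.rule_trace == r2.rule_trace


def test_single_pair_is_unambiguous(catalog):
    vec = _vec(catalog, "cB01|tA01-del10", "cB01|tA01-del10")
    res = phase_with_rules(enumerate_pairs(vec, catalog), vec, catalog)
    assert res.status == "unambiguous"
    assert res.chosen_pair == ("cB01|tA01-del10", "cB01|tA01-del10")


def test_empty_pairs_is_unresolved(catalog):
    res = phase_with_rules([], _vec(catalog, "cA01|tA01", "cA01|tA01"),
                           catalog)
    assert res.status == "unresolved"
    assert res.chosen_pair is None


def test_centromeric_block_placement_rule(catalog):
    """One 2DL5-2DS35 block with 2DP1 present and 3DS1 absent: every
    surviving pair places the block centromerically, and the trace records
    rule (ii)."""
    vec = _vec(catalog, "cB01|tA01", "cA01|tA01")
    res = phase_with_rules(enumerate_pairs(vec, catalog), vec, catalog)
    from kirhap.resolve import _block_residence
    for p1, p2 in res.consistent_pairs:
        sides = [s for s in (_block_residence(catalog[p1]),
                             _block_residence(catalog[p2])) if s]
        assert sides == ["centromeric"]
    assert any(rid == "rule-ii" for rid, _ in res.rule_trace)


def test_provisional_genotype_excluded(catalog, assays, solver):
    from kirhap.assays import PeakObservation
    dip, obs = noiseless_peaks(catalog, assays, "cB02|tA01", "cA01|tA01")
    def strip(ob):
        h = ob.as_dict()
        if (ob.assay_name, ob.position) == ("KIR-2DL2-N1", 126):
            h["G"] = 0.0
        if (ob.assay_name, ob.position) == ("KIR-2DS2-N1", 179):
            h["T"] = 0.0
        return PeakObservation.make(ob.sample_id, ob.assay_name,
                                    ob.position, h)
    call = integrate_assays([strip(o) for o in obs], assays, solver=solver)
    res = resolve_genotype(call, catalog)
    assert res.status == "excluded"
    assert not res.consistent_pairs


# -- novel inference -------------------------------------------------------

def test_infer_novel_refuses_resolvable_genotype(catalog):
    vec = _vec(catalog, "cA01|tA01", "cA01|tA01")
    with pytest.raises(AnalysisError):
        infer_novel(vec, catalog)


def test_leave_one_out_reconstruction(catalog):
    """Removing cB03|tA01 from the catalog and presenting a genotype that
    needs it yields its content as the top candidate at one edit."""
    reduced = CatalogTable(
        [r for r in catalog.records if r.name != "cB03|tA01"])
    vec = _vec(catalog, "cA01|tA01", "cB03|tA01")
    assert enumerate_pairs(vec, reduced) == []
    result = infer_novel(vec, reduced)
    assert result, "no candidate found"
    top = result[0]
    assert top.edit_count == 1
    assert top.reconstructed_name == "cB03|tA01"
    want = catalog["cB03|tA01"].content.as_dict()
    assert top.residual_content.as_dict() == want
    assert top.known_partner == "cA01|tA01"


@pytest.mark.parametrize("removed,partner", [
    ("cB01|tA01-del4", "cA01|tA01"),
    ("cB01|tA01-del10", "cB02|tB01"),
    ("cA01|tA01-hybd1", "cA01|tA01"),
    ("cA01|tB01-del7-3DL2p", "cB01|tA01"),
    ("cA01|tA01-ins4", "cA01|tA01"),
    ("cB03|tA01-ins5", "cB02|tB01"),
])
def test_leave_one_out_various_submotifs(catalog, removed, partner):
    """Every submotif class (deletion, insertion, hybridization, partial
    3DL2) is reconstructible from a genotype it leaves unexplained."""
    reduced = CatalogTable([r for r in catalog.records if r.name != removed])
    vec = _vec(catalog, removed, partner)
    assert enumerate_pairs(vec, reduced) == []
    result = infer_novel(vec, reduced)
    assert any(c.reconstructed_name == removed for c in result[:3])


def test_residual_without_3DL2_rejected(catalog):
    """A residual missing the telomeric framework end appears only in the
    diagnostics, never as a candidate."""
    counts = diplotype_counts(catalog, "cA01|tA01", "cA01|tA01")
    counts["3DL2"] -= 1  # strip one framework copy
    counts["2DS1"] = counts.get("2DS1", 0) + 1  # force non-catalog pattern
    vec = CopyVector.from_dict(counts, "diploid", collapse_2DS35=False)
    if enumerate_pairs(vec, catalog):
        pytest.skip("mutated vector unexpectedly resolvable")
    result = infer_novel(vec, catalog)
    partners = {c.known_partner for c in result}
    assert "cA01|tA01" not in partners or all(
        c.residual_content.get("3DL2")
        + c.residual_content.get("3DL1/L2")
        + c.residual_content.get("3DL2p") >= 1
        for c in result
    )
    assert result.diagnostics or result
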