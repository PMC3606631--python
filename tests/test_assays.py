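"""Assay table, peak forward model, ratio classification, integration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import diplotype_counts, noiseless_peaks
from kirhap.assays import (
    DEFAULT_RATIO_TOLERANCE,
    PeakObservation,
    RatioGroup,
    RatioRule,
    classify_ratio,
    coverage_report,
    expected_peaks,
    integrate_assays,
    load_assay_definitions,
    observable_projection,
)
from kirhap.errors import NoSignalError

FIVE_CLASSES = RatioRule(
    groups=(RatioGroup(("X",), 1, "A"), RatioGroup(("Y",), 1, "C")),
    classes=((1, 1), (2, 1), (3, 1), (3, 2), (4, 1)),
)


def test_fourteen_assays(assays):
    assert len(assays) == 14


def test_3DL1_002_distinguishes_85(assays):
    a = next(x for x in assays if x.name == "3DL1-002")
    assert a.carriers(85, "T") == ("3DL1",)
    assert a.carriers(85, "G") == ("3DS1",)


def test_coverage_at_least_two_targets(assays):
    report = coverage_report(assays)
    exempt = {"3DL3", "2DL4", "3DP1"}
    for locus, n in report.items():
        if locus in exempt or locus == "2DS35":
            continue
        assert n >= 2, locus


def test_coverage_report_after_removing_assay(assays):
    """Dropping the 2DP1-only amplicon yields a deterministic report in
    which 2DP1 retains its other confirmations."""
    reduced = [a for a in assays if a.name != "2DP1-002"]
    r1 = coverage_report(reduced)
    r2 = coverage_report(reduced)
    assert r1 == r2
    assert r1["2DP1"] == coverage_report(assays)["2DP1"] - 2
    assert r1["2DP1"] >= 2


# -- forward model ---------------------------------------------------------

def test_expected_peaks_homozygote_ratio_position_137(catalog, assays):
    dip = diplotype_counts(catalog, "cA01|tA01", "cA01|tA01")
    a = next(x for x in assays if x.name == "2DL2-001")
    gain = 3.0
    obs = {o.position: o for o in expected_peaks(dip, a, gain=gain)}
    # numerator 2DL3 x2, denominator 2DP1 x2 -> class 1:1 at equal heights
    assert obs[137].height("C") == pytest.approx(2 * gain)
    assert obs[137].height("T") == pytest.approx(2 * gain)
    rc = classify_ratio((obs[137].height("C"), obs[137].height("T")),
                        a.ratio_rules[0])
    assert rc.ratio_class == (1, 1)


def test_expected_peaks_heterozygote_three_to_two(catalog, assays):
    dip = diplotype_counts(catalog, "cB01|tA01", "cA01|tA01")
    a = next(x for x in assays if x.name == "2DL2-001")
    obs = {o.position: o for o in expected_peaks(dip, a)}
    rc = classify_ratio((obs[137].height("C"), obs[137].height("T")),
                        a.ratio_rules[0])
    assert rc.ratio_class == (3, 2)


def test_expected_peaks_absent_denominator(catalog, assays):
    """cB02|tB01 lacks 2DP1 entirely: the T peak at 137 is zero."""
    dip = diplotype_counts(catalog, "cB02|tB01", "cB02|tB01")
    a = next(x for x in assays if x.name == "2DL2-001")
    obs = {o.position: o for o in expected_peaks(dip, a)}
    assert obs[137].height("T") == 0.0
    rc = classify_ratio((obs[137].height("C"), obs[137].height("T")),
                        a.ratio_rules[0])
    assert rc.kind == "absent"
    assert rc.present == (True, False)


def test_hybrid_presents_parent_segment(catalog, assays):
    """The 2DS2/S3 hybrid (boundary intron 6) shows 2DS2 bases in the
    exon-4/5 assays but 2DS35 bases in the exon-7/8 assay."""
    dip = diplotype_counts(catalog, "cB01|tA01-del10", "cA01|tA01")
    e4 = next(x for x in assays if x.name == "2DS2-002")
    e78 = next(x for x in assays if x.name == "2DL3-006")
    obs4 = {o.position: o for o in expected_peaks(dip, e4)}
    obs78 = {o.position: o for o in expected_peaks(dip, e78)}
    assert obs4[89].height("A") == 1.0      # hybrid counts as 2DS2
    assert obs78[59].height("A") == 1.0     # and as 2DS35 at exon 7/8
    s35_e4 = next(x for x in assays if x.name == "2DS35-005")
    obs35 = {o.position: o for o in expected_peaks(dip, s35_e4)}
    assert obs35[247].height("T") == 0.0    # but not in the exon-4 2DS35 assay


# -- ratio classification --------------------------------------------------

@pytest.mark.parametrize(
    "heights,expected",
    [((1000.0, 1000.0), (1, 1)),
     ((1500.0, 1000.0), (3, 2)),
     ((2000.0, 1000.0), (2, 1)),
     ((4100.0, 1000.0), (4, 1))],
)
def test_classify_ratio_nearest_class(heights, expected):
    rc = classify_ratio(heights, FIVE_CLASSES)
    assert rc.kind == "class"
    assert rc.ratio_class == expected


def test_classify_ratio_unclassifiable_beyond_tolerance():
    rc = classify_ratio((5200.0, 1000.0), FIVE_CLASSES)
    assert rc.kind == "unclassifiable"
    assert rc.distance == pytest.approx(np.log(5.2) - np.log(4.0))


def test_classify_ratio_below_floor_is_absent():
    rc = classify_ratio((1000.0, 10.0), FIVE_CLASSES)
    assert rc.kind == "absent"
    assert rc.present == (True, False)


def test_classify_ratio_no_signal_raises():
    with pytest.raises(NoSignalError):
        classify_ratio((0.0, 0.0), FIVE_CLASSES)


@settings(max_examples=200, deadline=None)
@given(
    h1=st.floats(min_value=100.0, max_value=10000.0),
    h2=st.floats(min_value=100.0, max_value=10000.0),
    bump=st.floats(min_value=1.0, max_value=10.0),
)
def test_classify_ratio_monotone_in_numerator(h1, h2, bump):
    """Raising the numerator never moves the call to a smaller ratio."""
    def value(rc):
        if rc.kind == "absent":
            return float("inf") if rc.present[0] else -float("inf")
        if rc.kind == "class":
            return rc.ratio_class[0] / rc.ratio_class[1]
        return None
    lo = value(classify_ratio((h1, h2), FIVE_CLASSES))
    hi = value(classify_ratio((h1 * bump, h2), FIVE_CLASSES))
    if lo is not None and hi is not None:
        assert hi >= lo


def test_classify_gain_invariance():
    for g in (0.1, 1.0, 7.3):
        rc = classify_ratio((1500.0 * g, 1000.0 * g), FIVE_CLASSES)
        assert rc.ratio_class == (3, 2)


# -- integration -----------------------------------------------------------

def test_forward_backward_consistency_sampled(catalog, assays, solver):
    """Noiseless peaks of sampled catalog diplotypes integrate back to the
    true observable copy vector (full 703 coverage in the acceptance suite)."""
    names = catalog.names
    picks = [(names[i], names[j])
             for i, j in [(0, 0), (0, 18), (5, 11), (19, 20), (25, 30),
                          (36, 36), (12, 14)]]
    for h1, h2 in picks:
        dip, obs = noiseless_peaks(catalog, assays, h1, h2)
        call = integrate_assays(obs, assays, solver=solver)
        projs = [observable_projection(v.as_dict())
                 for v in call.candidate_vectors]
        assert observable_projection(dip) in projs, (h1, h2)
        assert not call.discordances


def test_single_confirmation_is_provisional(catalog, assays, solver):
    """A 2DL2 primary signal without its secondary confirmations leaves
    2DL2 provisional with evidence 1."""
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
    assert call.presence_evidence.get("2DL2") == 1
    assert "2DL2" in call.provisional_loci


def test_contradictory_ratios_recorded_as_discordance(catalog, assays, solver):
    """Doubling one assay's 2DP1 peak makes its copy ratio contradict the
    other assays; the conflict is recorded, not silently resolved."""
    dip, obs = noiseless_peaks(catalog, assays, "cA01|tA01", "cA01|tA01")
    def spike(ob):
        if (ob.assay_name, ob.position) == ("2DL2-001", 137):
            h = ob.as_dict()
            h["T"] *= 2.0
            return PeakObservation.make(ob.sample_id, ob.assay_name,
                                        ob.position, h)
        return ob
    call = integrate_assays([spike(o) for o in obs], assays, solver=solver)
    assert call.discordances
    assert any(d[1] == "2DL2-001" for d in call.discordances)


def test_noise_robustness_frozen_bounds(catalog, assays, solver):
    """At lognormal peak noise sigma=0.1 the raw ratio classifications are
    right >=85% of the time, while the integrated per-locus genotype
    accuracy exceeds 99% (constraint redundancy absorbs single-ratio
    errors).  Bounds frozen from a 400-sample measurement at this seed."""
    from kirhap.simulate import (SimulationConfig, realize_diplotype,
                                 sample_cohort, simulate_peaks)
    from kirhap.assays import build_signature

    cfg = SimulationConfig(n_individuals=400, seed=7, peak_noise_sigma=0.1)
    cohort = sample_cohort(cfg, catalog)
    rng = np.random.default_rng(np.random.SeedSequence([7, 1]))
    ratio_ok = ratio_tot = locus_ok = locus_tot = 0
    for sid, h1, h2 in cohort:
        state = rng.bit_generator.state
        dip = realize_diplotype(h1, h2, catalog, rng=rng, p_2DS3=cfg.p_2DS3)
        rng.bit_generator.state = state
        obs = simulate_peaks((h1, h2), assays, cfg, catalog, rng=rng,
                             sample_id=sid)
        noisy = build_signature(obs, assays)
        clean_obs = [o for a in assays for o in expected_peaks(dip, a)]
        clean = build_signature(clean_obs, assays)
        for k, v in clean.ratios.items():
            ratio_tot += 1
            ratio_ok += noisy.ratios.get(k) == v
        call = integrate_assays(obs, assays, solver=solver)
        got = observable_projection(call.copies.as_dict())
        want = observable_projection(dip)
        for a, b in zip(got, want):
            locus_tot += 1
            locus_ok += a == b
    assert ratio_ok / ratio_tot >= 0.85
    assert locus_ok / locus_tot >= 0.99
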