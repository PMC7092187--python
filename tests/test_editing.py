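"""Immunoediting statistics: exact distributions and per-level estimators."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neoedit.editing import (
    CohortError,
    CohortTable,
    affinity_comparison,
    allele_editing,
    allele_editing_table,
    classify_group,
    editing_scores,
    fdr_adjust,
    histology_editing,
    patient_editing,
    poisson_binomial_cdf,
    poisson_binomial_pmf,
    silent_enrichment,
    variant_editing,
)
from neoedit.presentation import AlleleFrequencyTable, PresentationMap
from neoedit.windows import PeptideWindow


@pytest.fixture()
def toy_freqs():
    return AlleleFrequencyTable(
        pd.DataFrame(
            {
                "allele": ["A*01:01", "A*02:01", "B*01:01", "C*01:01"],
                "locus": ["A", "A", "B", "C"],
                "frequency": [0.3, 0.2, 0.25, 0.4],
            }
        )
    )


def _cohort(rows, membership):
    patients = pd.DataFrame(
        rows, columns=["patient_id", "histology", "A1", "A2", "B1", "B2", "C1", "C2"]
    )
    member = pd.DataFrame(membership, columns=["patient_id", "variant_id"])
    return CohortTable(patients, member)


@pytest.fixture()
def toy_cohort():
    # p1/p2 carry A*01:01; p3/p4 do not
    rows = [
        ("p1", "glioma", "A*01:01", "A*02:01", "B*01:01", "B*01:01", "C*01:01", "C*01:01"),
        ("p2", "glioma", "A*01:01", "A*01:01", "B*01:01", "B*01:01", "C*01:01", "C*01:01"),
        ("p3", "uterine", "A*02:01", "A*02:01", "B*01:01", "B*01:01", "C*01:01", "C*01:01"),
        ("p4", "uterine", "A*02:01", "A*02:01", "B*01:01", "B*01:01", "C*01:01", "C*01:01"),
    ]
    membership = [
        ("p1", "v_bound"), ("p2", "v_bound"), ("p3", "v_bound"), ("p4", "v_bound"),
        ("p1", "v_silent"), ("p3", "v_silent"),
    ]
    return _cohort(rows, membership)


@pytest.fixture()
def toy_pmap(toy_freqs):
    return PresentationMap.from_sets(
        {"v_bound": ["A*01:01"], "v_silent": []}, toy_freqs
    )


# ---------------------------------------------------------------------------
# exact distributions


def test_poisson_binomial_matches_enumeration():
    rng = np.random.default_rng(0)
    for n in (1, 5, 10, 15):
        ps = rng.uniform(0, 1, n)
        pmf = poisson_binomial_pmf(ps)
        brute = np.zeros(n + 1)
        for bits in itertools.product([0, 1], repeat=n):
            prob = np.prod([p if b else 1 - p for p, b in zip(ps, bits)])
            brute[sum(bits)] += prob
        np.testing.assert_allclose(pmf, brute, atol=1e-12)
        k = n // 2
        assert poisson_binomial_cdf(k, ps) == pytest.approx(brute[: k + 1].sum())


def test_poisson_binomial_reduces_to_binomial():
    ps = [0.3] * 12
    for k in range(13):
        assert poisson_binomial_cdf(k, ps) == pytest.approx(
            stats.binom.cdf(k, 12, 0.3), abs=1e-12
        )


def test_fdr_adjust_hand_examples():
    assert fdr_adjust([0.05]) == pytest.approx([0.05])
    np.testing.assert_allclose(
        fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
    # q monotone non-decreasing in sorted p
    rng = np.random.default_rng(1)
    p = np.sort(rng.uniform(0, 1, 30))
    q = fdr_adjust(p)
    assert (np.diff(q) >= -1e-12).all()


# ---------------------------------------------------------------------------
# allele level


def test_allele_editing_observed_vs_expected(toy_cohort, toy_pmap, toy_freqs):
    res = allele_editing(toy_cohort, toy_pmap, toy_freqs, "A*01:01")
    # all four patients harbor v_bound; two carry the allele
    assert res.n == 4
    assert res.observed == pytest.approx(0.5)
    expected = 1 - (1 - 0.3) ** 2
    assert res.expected == pytest.approx(expected)
    assert res.ratio == pytest.approx(0.5 / expected)
    assert res.p == pytest.approx(stats.binom.cdf(2, 4, expected))


def test_allele_editing_no_eligible_patients_flagged(toy_cohort, toy_pmap, toy_freqs):
    res = allele_editing(toy_cohort, toy_pmap, toy_freqs, "B*01:01")
    assert not res.tested
    assert np.isnan(res.ratio)


def test_allele_editing_allelic_mode(toy_cohort, toy_pmap, toy_freqs):
    res = allele_editing(toy_cohort, toy_pmap, toy_freqs, "A*01:01", mode="allelic")
    # copies: p1 has 1, p2 has 2 -> 3 of 8
    assert res.observed == pytest.approx(3 / 8)
    assert res.expected == pytest.approx(0.3)


def test_allele_editing_table_fdr(toy_cohort, toy_pmap, toy_freqs):
    table = allele_editing_table(toy_cohort, toy_pmap, toy_freqs, min_allele_freq=0.0)
    tested = table[table["note"].isna()]
    np.testing.assert_allclose(
        tested["q"].to_numpy(), fdr_adjust(tested["p"].to_numpy())
    )


def test_editing_scores_products(toy_freqs):
    results = pd.DataFrame(
        [
            {"unit": "A*01:01", "ratio": 0.56, "note": None},
            {"unit": "A*02:01", "ratio": 1.2, "note": None},
        ]
    )
    breadths = {"A*01:01": 0.10, "A*02:01": 0.30}
    out = editing_scores(results, breadths, toy_freqs).set_index("allele")
    assert out.loc["A*01:01", "underrepresentation"] == pytest.approx(0.44)
    assert out.loc["A*01:01", "editing_score"] == pytest.approx(0.044)
    assert out.loc["A*01:01", "population_contribution"] == pytest.approx(0.044 * 0.3)
    # over-represented allele clamps to zero
    assert out.loc["A*02:01", "underrepresentation"] == 0.0
    assert out.loc["A*02:01", "editing_score"] == 0.0


# ---------------------------------------------------------------------------
# variant level


def test_variant_editing_zero_carrier_closed_form(toy_freqs):
    """Observed 0 of n reproduces (1 - p_v)^n exactly."""
    n = 20
    rows = [
        (f"p{i}", "x", "A*02:01", "A*02:01", "B*01:01", "B*01:01", "C*01:01", "C*01:01")
        for i in range(n)
    ]
    membership = [(f"p{i}", "v") for i in range(n)]
    cohort = _cohort(rows, membership)
    pmap = PresentationMap.from_sets({"v": ["A*01:01"]}, toy_freqs)
    res = variant_editing("v", cohort, pmap, toy_freqs)
    p_v = 1 - (1 - 0.3) ** 2
    assert res.observed == 0
    assert res.ratio == 0.0
    assert res.p == pytest.approx((1 - p_v) ** n, rel=1e-9)


def test_variant_editing_silent_skipped(toy_cohort, toy_pmap, toy_freqs):
    res = variant_editing("v_silent", toy_cohort, toy_pmap, toy_freqs)
    assert not res.tested
    assert res.expected == 0.0


def test_variant_editing_counts_carrying_occurrences(toy_cohort, toy_pmap, toy_freqs):
    res = variant_editing("v_bound", toy_cohort, toy_pmap, toy_freqs)
    assert res.n == 4
    assert res.observed == 2  # p1 and p2 carry A*01:01
    p_v = 1 - (1 - 0.3) ** 2
    assert res.expected == pytest.approx(4 * p_v)
    assert res.p == pytest.approx(stats.binom.cdf(2, 4, p_v))


# ---------------------------------------------------------------------------
# patient and histology level


def test_patient_editing_full_match_ratio_ge_one(toy_cohort, toy_pmap, toy_freqs):
    res = patient_editing("p1", toy_cohort, toy_pmap, toy_freqs)
    # p1 presents its single non-silent variant
    assert res.observed == 1
    assert res.ratio >= 1


def test_patient_editing_binomial_special_case(toy_freqs):
    """All p_i = 0.51, 10 variants, observed 5 -> exact binomial lower tail."""
    sets = {f"v{i}": ["A*01:01"] for i in range(10)}
    pmap = PresentationMap.from_sets(sets, toy_freqs)
    p_one = pmap.carrier_prob("v0")
    rows = [("p1", "x", "A*01:01", "A*02:01", "B*01:01", "B*01:01", "C*01:01", "C*01:01")]
    membership = [("p1", f"v{i}") for i in range(10)]
    cohort = _cohort(rows, membership)
    res = patient_editing("p1", cohort, pmap, toy_freqs)
    # p1 carries the binding allele, so all 10 are presented
    assert res.observed == 10
    assert res.expected == pytest.approx(10 * p_one)
    assert res.p == pytest.approx(stats.binom.cdf(10, 10, p_one))


def test_patient_with_only_silent_variants_flagged(toy_freqs):
    pmap = PresentationMap.from_sets({"v": []}, toy_freqs)
    rows = [("p1", "x", "A*01:01", "A*01:01", "B*01:01", "B*01:01", "C*01:01", "C*01:01")]
    cohort = _cohort(rows, [("p1", "v")])
    res = patient_editing("p1", cohort, pmap, toy_freqs)
    assert not res.tested


def test_histology_pools_patient_expectations(toy_cohort, toy_pmap, toy_freqs):
    res_hist = histology_editing(toy_cohort, "glioma", toy_pmap, toy_freqs)
    p1 = patient_editing("p1", toy_cohort, toy_pmap, toy_freqs)
    p2 = patient_editing("p2", toy_cohort, toy_pmap, toy_freqs)
    assert res_hist.expected == pytest.approx(p1.expected + p2.expected)
    assert res_hist.observed == p1.observed + p2.observed
    # single-patient histology equals that patient's test
    solo = _cohort(
        [("p9", "solo", "A*01:01", "A*01:01", "B*01:01", "B*01:01", "C*01:01", "C*01:01")],
        [("p9", "v_bound")],
    )
    res_solo = histology_editing(solo, "solo", toy_pmap, toy_freqs)
    res_pat = patient_editing("p9", solo, toy_pmap, toy_freqs)
    assert res_solo.expected == pytest.approx(res_pat.expected)
    assert res_solo.p == pytest.approx(res_pat.p)


def test_histology_specific_editing_ranks_most_depleted(toy_freqs):
    """A histology simulated with strong editing shows the lowest ratio."""
    from neoedit.simulate import SimulationConfig, simulate_cohort

    sets = {f"v{i}": ["A*01:01"] for i in range(20)}
    sets.update({f"u{i}": [] for i in range(5)})
    pmap = PresentationMap.from_sets(sets, toy_freqs)
    variants = list(sets)
    base = dict(
        n_patients=150, n_variants=len(variants), mean_variants_per_patient=4.0
    )
    cfg_edit = SimulationConfig(seed=7, editing_efficiency=0.9,
                                histologies=("edited",), **base)
    cfg_null = SimulationConfig(seed=8, editing_efficiency=0.0,
                                histologies=("unedited",), **base)
    rng = np.random.default_rng(9)
    c1 = simulate_cohort(cfg_edit, toy_freqs, variants, pmap, rng)
    c2 = simulate_cohort(cfg_null, toy_freqs, variants, pmap, rng)
    patients = pd.concat([c1.patients, c2.patients.assign(
        patient_id=c2.patients["patient_id"] + "b")], ignore_index=True)
    membership = pd.concat(
        [c1.membership, c2.membership.assign(
            patient_id=c2.membership["patient_id"] + "b")], ignore_index=True)
    merged = CohortTable(patients, membership)
    r_edit = histology_editing(merged, "edited", pmap, toy_freqs)
    r_null = histology_editing(merged, "unedited", pmap, toy_freqs)
    assert r_edit.ratio < r_null.ratio
    assert r_edit.p < r_null.p


# ---------------------------------------------------------------------------
# silence enrichment, groups, affinities


def test_silent_enrichment_null_and_boosted(toy_freqs):
    # every variant occurs once -> observed equals baseline
    sets = {"a": ["A*01:01"], "b": []}
    pmap = PresentationMap.from_sets(sets, toy_freqs)
    rows = [("p1", "x", "A*01:01", "A*01:01", "B*01:01", "B*01:01", "C*01:01", "C*01:01")]
    cohort = _cohort(rows, [("p1", "a"), ("p1", "b")])
    obs, base, p = silent_enrichment(cohort, pmap)
    assert obs == base == 0.5
    assert p > 0.5
    # silent variant occurring 10x as often -> enrichment detected
    membership = [("p1", "a")] + [(f"p{i}", "b") for i in range(10)]
    rows = [
        (f"p{i}", "x", "A*01:01", "A*01:01", "B*01:01", "B*01:01", "C*01:01", "C*01:01")
        for i in range(10)
    ] + [("p1b", "x", "A*01:01", "A*01:01", "B*01:01", "B*01:01", "C*01:01", "C*01:01")]
    membership = [("p1b", "a")] + [(f"p{i}", "b") for i in range(10)]
    cohort10 = _cohort(rows, membership)
    obs10, base10, p10 = silent_enrichment(cohort10, pmap)
    assert obs10 == pytest.approx(10 / 11)
    assert base10 == 0.5
    assert p10 < 0.05


def test_silent_enrichment_skipped_without_silent_variants(toy_freqs):
    pmap = PresentationMap.from_sets({"a": ["A*01:01"]}, toy_freqs)
    rows = [("p1", "x", "A*01:01", "A*01:01", "B*01:01", "B*01:01", "C*01:01", "C*01:01")]
    cohort = _cohort(rows, [("p1", "a")])
    obs, base, p = silent_enrichment(cohort, pmap)
    assert obs == base == 0.0
    assert np.isnan(p)


@pytest.mark.parametrize("offset,group", [(1, 1), (2, 2), (5, 1), (8, 1), (9, 2)])
def test_classify_group_anchor_positions(offset, group):
    w = PeptideWindow(variant_id="v", start=1, mutant="A" * 9, wildtype="A" * 9,
                      offset=offset)
    assert classify_group(w) == group
    assert classify_group(offset) == group


def test_affinity_comparison_identical_and_shifted():
    rng0 = np.random.default_rng(2)
    same = np.exp(rng0.normal(np.log(800), 0.4, 30))
    summaries = pd.DataFrame(
        {
            "allele": ["X"] * 30 + ["Y"] * 30,
            "best_affinity": np.concatenate([same, same]),
            "strong": True,
        }
    )
    m1, m2, p = affinity_comparison(["X"], ["Y"], summaries)
    assert m1 == pytest.approx(m2)
    assert p > 0.99
    rng = np.random.default_rng(4)
    shifted = pd.DataFrame(
        {
            "allele": ["X"] * 50 + ["Y"] * 50,
            "best_affinity": np.concatenate(
                [np.exp(rng.normal(np.log(500), 0.3, 50)),
                 np.exp(rng.normal(np.log(1500), 0.3, 50))]
            ),
            "strong": True,
        }
    )
    m1, m2, p = affinity_comparison(["X"], ["Y"], shifted)
    assert m1 < m2
    assert p < 1e-6
    with pytest.raises(ValueError, match="both allele groups"):
        affinity_comparison(["Z"], ["Y"], shifted)


def test_cohort_table_validation(toy_cohort):
    with pytest.raises(CohortError, match="unknown patient"):
        toy_cohort.genotype("nobody")
    with pytest.raises(CohortError, match="duplicate"):
        CohortTable(
            pd.concat([toy_cohort.patients, toy_cohort.patients]),
            toy_cohort.membership,
        )
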