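"""PPIDR/MDS statistics, CDF calls, CH-CDF quadrants, and cohort reports."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from stemdis.classify import (
    DEFAULT_CDF_BOUNDARY,
    ProteinDisorderSummary,
    bin_protein,
    cdf_distance,
    ch_cdf_quadrant,
    cohort_summary,
    mds,
    ppidr,
    residue_flexibility_classes,
    round_half_up,
)
from stemdis.disorder import DisorderProfile

score_vectors = arrays(
    float,
    st.integers(min_value=1, max_value=200),
    elements=st.floats(min_value=0, max_value=1, allow_nan=False),
)


def profile(scores):
    return DisorderProfile("p", np.asarray(scores, dtype=float))


@pytest.mark.parametrize(
    "scores,expected",
    [([0.6, 0.6, 0.4, 0.2], 50.0), ([0.5] * 8, 0.0), ([0.9] * 5, 100.0)],
)
def test_ppidr(scores, expected):
    assert ppidr(profile(scores)) == pytest.approx(expected)


def test_mds_simple():
    assert mds(profile([0.6, 0.6, 0.4, 0.2])) == pytest.approx(0.45)
    assert mds(profile([0.3] * 11)) == pytest.approx(0.3)


@pytest.mark.parametrize(
    "scores,expected",
    [
        ([0.6, 0.3, 0.2, 0.1], {"disordered": 1, "highly_flexible": 1,
                                "flexible": 1, "other": 1}),
        ([0.0] * 6, {"disordered": 0, "highly_flexible": 0,
                     "flexible": 0, "other": 6}),
    ],
)
def test_flexibility_classes(scores, expected):
    assert residue_flexibility_classes(profile(scores)) == expected


@given(score_vectors)
def test_statistics_match_bruteforce_oracle(scores):
    prof = profile(scores)
    assert ppidr(prof) == pytest.approx(
        100 * sum(1 for s in scores if s > 0.5) / len(scores), abs=1e-9
    )
    assert mds(prof) == pytest.approx(sum(scores) / len(scores), abs=1e-12)
    counts = {"disordered": 0, "highly_flexible": 0, "flexible": 0, "other": 0}
    for s in scores:
        if s > 0.5:
            counts["disordered"] += 1
        elif s >= 0.25:
            counts["highly_flexible"] += 1
        elif s >= 0.15:
            counts["flexible"] += 1
        else:
            counts["other"] += 1
    assert residue_flexibility_classes(prof) == counts
    assert sum(counts.values()) == len(scores)


@given(score_vectors, st.integers(min_value=0, max_value=10_000))
def test_raising_a_score_never_lowers_ppidr_or_mds(scores, pos):
    prof = profile(scores)
    i = pos % len(scores)
    raised = scores.copy()
    raised[i] = min(1.0, raised[i] + 0.3)
    prof2 = profile(raised)
    assert ppidr(prof2) >= ppidr(prof)
    assert mds(prof2) >= mds(prof) - 1e-12


@pytest.mark.parametrize(
    "p,m,expected",
    [
        (24.2, 0.3, ("moderately_disordered", "moderately_disordered")),
        (10.0, 0.25, ("moderately_disordered", "moderately_disordered")),
        (97.6, 0.9, ("highly_disordered", "highly_disordered")),
        (0.0, 0.0, ("highly_ordered", "highly_ordered")),
        (30.0, 0.5, ("highly_disordered", "highly_disordered")),
        (9.999, 0.2499, ("highly_ordered", "highly_ordered")),
    ],
)
def test_bin_protein_thresholds(p, m, expected):
    assert bin_protein(p, m) == expected


def test_bin_protein_rejects_out_of_range():
    with pytest.raises(ValueError):
        bin_protein(101.0, 0.5)
    with pytest.raises(ValueError):
        bin_protein(50.0, 1.5)


class TestCDF:
    def test_all_ordered(self):
        dist, disordered = cdf_distance(profile([0.0] * 10))
        assert dist > 0 and not disordered

    def test_all_disordered(self):
        dist, disordered = cdf_distance(profile([1.0] * 10))
        assert dist < 0 and disordered

    def test_on_boundary_point(self):
        dist, disordered = cdf_distance(
            profile([0.2, 0.4, 0.6, 0.8]), boundary=[(0.5, 0.5)]
        )
        assert dist == pytest.approx(0.0)
        assert not disordered

    def test_empty_or_malformed_boundary(self):
        with pytest.raises(ValueError):
            cdf_distance(profile([0.5]), boundary=[])
        with pytest.raises(ValueError):
            cdf_distance(profile([0.5]), boundary=[(1.5, 0.5)])


@pytest.mark.parametrize(
    "ch,cdf,expected",
    [
        (-0.3, 0.1, "Q1"),
        (-0.3, -0.1, "Q2"),
        (0.3, -0.1, "Q3"),
        (0.3, 0.1, "Q4"),
        (0.0, 0.0, "Q2"),  # ties resolve to the ordered side of each axis
        (0.0, 0.1, "Q1"),
    ],
)
def test_quadrants(ch, cdf, expected):
    assert ch_cdf_quadrant(ch, cdf) == expected


def test_quadrant_rejects_non_finite():
    with pytest.raises(ValueError):
        ch_cdf_quadrant(float("nan"), 0.0)


def _summary(pid, quadrant, p, m):
    pb, mb = bin_protein(p, m)
    ch = 0.3 if quadrant in ("Q3", "Q4") else -0.3
    cdf = 0.1 if quadrant in ("Q1", "Q4") else -0.1
    assert ch_cdf_quadrant(ch, cdf) == quadrant
    return ProteinDisorderSummary(pid, p, m, ch, cdf, quadrant, pb, mb)


class TestCohortSummary:
    def test_counts_conserved_and_match_bruteforce(self):
        rng = np.random.default_rng(42)
        summaries = []
        for i in range(50):
            q = ("Q1", "Q2", "Q3", "Q4")[rng.integers(4)]
            summaries.append(
                _summary(f"P{i}", q, float(rng.uniform(0, 100)),
                         float(rng.uniform(0, 1)))
            )
        rep = cohort_summary(summaries, "c")
        assert sum(rep.quadrant_counts.values()) == 50
        assert sum(rep.ppidr_bin_counts.values()) == 50
        assert sum(rep.mds_bin_counts.values()) == 50
        # independent brute-force tallies
        for q in ("Q1", "Q2", "Q3", "Q4"):
            assert rep.quadrant_counts[q] == sum(1 for s in summaries if s.quadrant == q)
        expected_pct = round_half_up(
            100 * sum(1 for s in summaries if s.quadrant in ("Q2", "Q3")) / 50
        )
        assert rep.percent_high_disorder_chcdf == expected_pct
        assert rep.n_stringent_ppidr50 == sum(1 for s in summaries if s.ppidr >= 50)
        top = sorted((s.ppidr for s in summaries), reverse=True)[:10]
        assert rep.top10_ppidr_range == (top[0], top[-1])

    def test_all_q1_cohort_has_zero_high_disorder(self):
        summaries = [_summary(f"P{i}", "Q1", 5.0, 0.1) for i in range(8)]
        assert cohort_summary(summaries, "c").percent_high_disorder_chcdf == 0.0

    def test_stored_bins_reproducible_from_values(self):
        s = _summary("P", "Q2", 24.2, 0.3)
        assert bin_protein(s.ppidr, s.mds) == (s.ppidr_bin, s.mds_bin)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([], "c")


def test_round_half_up_behaviour():
    assert round_half_up(37.714285) == 37.7
    assert round_half_up(31.0502) == 31.1
    assert round_half_up(0.05, 1) == 0.1  # half rounds away from zero
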