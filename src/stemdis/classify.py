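"""Protein-level disorder classification and cohort reporting.

From a per-residue disorder profile this module derives:

* PPIDR — percent of predicted intrinsically disordered residues, i.e. the
  fraction of residues scoring strictly above 0.5, times 100;
* MDS — mean disorder score over the protein;
* residue flexibility classes (disordered > 0.5; highly flexible 0.25–0.5;
  flexible 0.15–0.25; other < 0.15);
* a CDF call — the cumulative distribution of residue scores compared against
  a boundary curve; a protein whose CDF runs below the boundary has many
  high-scoring residues and is called disordered;
* the CH–CDF quadrant combining the CH-plot distance (Y) with the signed CDF
  distance (X, ordered-positive): Q1 ordered by both, Q2 compact-by-CH but
  disordered-by-CDF (molten globule / hybrid), Q3 disordered by both, Q4
  disordered-by-CH but ordered-by-CDF.

Proteins are binned three ways on either statistic: highly ordered
(PPIDR < 10% or MDS < 0.25), moderately disordered (10% ≤ PPIDR < 30% or
0.25 ≤ MDS < 0.5), highly disordered (PPIDR ≥ 30% or MDS ≥ 0.5).  Cohort
reports tally quadrants and bins and derive the headline percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np

from .disorder import (
    CH_A_DEFAULT,
    CH_B_DEFAULT,
    DisorderProfile,
    ProteinRecord,
    ch_distance,
    residue_disorder_profile,
)

__all__ = [
    "DEFAULT_CDF_BOUNDARY",
    "ProteinDisorderSummary",
    "CohortDisorderReport",
    "ppidr",
    "mds",
    "residue_flexibility_classes",
    "bin_protein",
    "cdf_distance",
    "ch_cdf_quadrant",
    "summarize_protein",
    "cohort_summary",
    "round_half_up",
]

#: Default CDF boundary: 7 evenly spaced score thresholds on [0.2, 0.8] with
#: boundary fractions rising linearly from 0.6 to 0.9.  Overridable wherever a
#: boundary is accepted.
DEFAULT_CDF_BOUNDARY: tuple[tuple[float, float], ...] = tuple(
    (round(t, 2), round(f, 3))
    for t, f in zip(np.linspace(0.2, 0.8, 7), np.linspace(0.6, 0.9, 7))
)

_BIN_NAMES = ("highly_ordered", "moderately_disordered", "highly_disordered")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, used for every reported percentage."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def ppidr(profile: DisorderProfile) -> float:
    """Percent of residues with disorder score strictly above 0.5."""
    return 100.0 * float(np.count_nonzero(profile.scores > 0.5)) / len(profile)


def mds(profile: DisorderProfile) -> float:
    """Mean disorder score of the protein."""
    return float(np.mean(profile.scores))


def residue_flexibility_classes(profile: DisorderProfile) -> dict[str, int]:
    """Count residues per flexibility class.

    disordered: score > 0.5; highly_flexible: 0.25 ≤ score ≤ 0.5;
    flexible: 0.15 ≤ score < 0.25; other: score < 0.15.  Class boundaries take
    the inclusive-lower convention so the counts always sum to the length.
    """
    s = profile.scores
    return {
        "disordered": int(np.count_nonzero(s > 0.5)),
        "highly_flexible": int(np.count_nonzero((s >= 0.25) & (s <= 0.5))),
        "flexible": int(np.count_nonzero((s >= 0.15) & (s < 0.25))),
        "other": int(np.count_nonzero(s < 0.15)),
    }


def _bin_value(x: float, lo: float, hi: float) -> str:
    if x < lo:
        return "highly_ordered"
    if x < hi:
        return "moderately_disordered"
    return "highly_disordered"


def bin_protein(ppidr_value: float, mds_value: float) -> tuple[str, str]:
    """Assign the PPIDR bin (10% / 30% cuts) and MDS bin (0.25 / 0.5 cuts).

    Lower edges are inclusive: PPIDR 10.0 and MDS 0.25 are moderately
    disordered; PPIDR 30.0 and MDS 0.5 are highly disordered.
    """
    if not 0.0 <= ppidr_value <= 100.0:
        raise ValueError(f"PPIDR out of range: {ppidr_value}")
    if not 0.0 <= mds_value <= 1.0:
        raise ValueError(f"MDS out of range: {mds_value}")
    return _bin_value(ppidr_value, 10.0, 30.0), _bin_value(mds_value, 0.25, 0.5)


def cdf_distance(
    profile: DisorderProfile,
    boundary: Sequence[tuple[float, float]] = DEFAULT_CDF_BOUNDARY,
) -> tuple[float, bool]:
    """Signed mean distance of the score CDF from a boundary curve.

    ``CDF(t)`` is the fraction of residues scoring ≤ t.  The distance is the
    mean of ``CDF(t) − fraction`` over boundary points: positive when the
    curve runs above the boundary (mostly low scores — ordered side), negative
    for disordered.  Returns ``(distance, disordered_by_cdf)`` where the call
    is ``distance < 0``.
    """
    if not boundary:
        raise ValueError("empty CDF boundary")
    pts = [(float(t), float(f)) for t, f in boundary]
    for t, f in pts:
        if not (0.0 <= t <= 1.0) or not np.isfinite(f):
            raise ValueError(f"malformed boundary point ({t}, {f})")
    s = profile.scores
    n = len(s)
    dist = float(
        np.mean([np.count_nonzero(s <= t) / n - f for t, f in pts])
    )
    return dist, dist < 0


def ch_cdf_quadrant(ch_dist: float, cdf_x: float) -> str:
    """CH–CDF quadrant from the CH distance (Y) and CDF distance (X).

    Y > 0 means disordered by CH; X > 0 means ordered by CDF.  Boundary ties
    (zero) resolve to the ordered side of each axis.
    """
    if not (math.isfinite(ch_dist) and math.isfinite(cdf_x)):
        raise ValueError("non-finite CH/CDF coordinates")
    if ch_dist <= 0:
        return "Q1" if cdf_x > 0 else "Q2"
    return "Q3" if cdf_x <= 0 else "Q4"


@dataclass(frozen=True)
class ProteinDisorderSummary:
    """One protein's disorder statistics and categorical calls."""

    protein_id: str
    ppidr: float
    mds: float
    ch_distance: float
    cdf_distance: float
    quadrant: str
    ppidr_bin: str
    mds_bin: str

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_protein(
    record: ProteinRecord,
    profile: DisorderProfile | None = None,
    *,
    window: int = 51,
    ch_a: float = CH_A_DEFAULT,
    ch_b: float = CH_B_DEFAULT,
    cdf_boundary: Sequence[tuple[float, float]] = DEFAULT_CDF_BOUNDARY,
) -> ProteinDisorderSummary:
    """Full per-protein classification.

    When ``profile`` is None the internal windowed scorer supplies it;
    externally read tracks may be passed instead.
    """
    if profile is None:
        profile = residue_disorder_profile(record, window=window, a=ch_a, b=ch_b)
    p = ppidr(profile)
    m = mds(profile)
    chp = ch_distance(record.sequence, a=ch_a, b=ch_b)
    cdf_x, _ = cdf_distance(profile, cdf_boundary)
    pb, mb = bin_protein(p, m)
    return ProteinDisorderSummary(
        protein_id=record.id,
        ppidr=p,
        mds=m,
        ch_distance=chp.ch_distance,
        cdf_distance=cdf_x,
        quadrant=ch_cdf_quadrant(chp.ch_distance, cdf_x),
        ppidr_bin=pb,
        mds_bin=mb,
    )


@dataclass
class CohortDisorderReport:
    """Aggregate disorder report for a cohort of proteins.

    ``percent_high_disorder_chcdf`` is the CH–CDF headline figure
    100·(|Q2| + |Q3|)/n: proteins disordered by CDF, i.e. either extended
    disorder (Q3) or molten-globule/hybrid (Q2).  Percentages are rounded
    half-up to one decimal for reporting.
    """

    cohort_name: str
    n: int
    quadrant_counts: dict[str, int]
    ppidr_bin_counts: dict[str, int]
    mds_bin_counts: dict[str, int]
    percent_high_disorder_chcdf: float
    percent_mod_or_high_ppidr: float
    percent_mod_or_high_mds: float
    n_stringent_ppidr50: int
    top10_ppidr_range: tuple[float, float]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["top10_ppidr_range"] = list(self.top10_ppidr_range)
        return d


def cohort_summary(
    summaries: Sequence[ProteinDisorderSummary], cohort_name: str
) -> CohortDisorderReport:
    """Tally quadrants and bins for a cohort and derive headline percentages."""
    if not summaries:
        raise ValueError("empty cohort")
    n = len(summaries)
    quad = {q: 0 for q in ("Q1", "Q2", "Q3", "Q4")}
    pbins = {b: 0 for b in _BIN_NAMES}
    mbins = {b: 0 for b in _BIN_NAMES}
    for s in summaries:
        quad[s.quadrant] += 1
        pbins[s.ppidr_bin] += 1
        mbins[s.mds_bin] += 1
    ppidrs = sorted((s.ppidr for s in summaries), reverse=True)
    top10 = ppidrs[: min(10, n)]
    return CohortDisorderReport(
        cohort_name=cohort_name,
        n=n,
        quadrant_counts=quad,
        ppidr_bin_counts=pbins,
        mds_bin_counts=mbins,
        percent_high_disorder_chcdf=round_half_up(
            100.0 * (quad["Q2"] + quad["Q3"]) / n
        ),
        percent_mod_or_high_ppidr=round_half_up(
            100.0 * sum(1 for s in summaries if s.ppidr >= 10.0) / n
        ),
        percent_mod_or_high_mds=round_half_up(
            100.0 * sum(1 for s in summaries if s.mds >= 0.25) / n
        ),
        n_stringent_ppidr50=sum(1 for s in summaries if s.ppidr >= 50.0),
        top10_ppidr_range=(top10[0], top10[-1]),
    )
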