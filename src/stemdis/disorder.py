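"""Sequence-level charge–hydropathy statistics and per-residue disorder scores.

Intrinsically disordered proteins are depleted in hydrophobic residues and
enriched in charged ones.  Two classic whole-protein coordinates exploit this:

* mean Kyte–Doolittle hydropathy, min–max scaled to [0, 1] (``H``), and
* mean absolute net charge per residue at neutral pH (``R``).

In the charge–hydropathy (CH) plot, extended-disorder proteins sit above the
empirical boundary line ``R = a·H − b`` (default ``a = 2.785``, ``b = 1.151``),
compact/ordered proteins below it.  The signed distance of a protein from the
boundary, positive on the disordered side, is the Y-coordinate of the CH–CDF
quadrant analysis performed downstream.

The per-residue scorer is a FoldIndex-style sliding-window statistic: within a
window the foldability index ``FI = a·H_w − |R_w| − b`` is positive for
foldable composition and negative for disordered composition; the disorder
score is ``clamp(0.5 − FI, 0, 1)``.  It is a closed-form, composition-based
scorer; score tracks produced by external trained predictors can be ingested
instead via :func:`read_score_track`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KYTE_DOOLITTLE",
    "ProteinRecord",
    "DisorderProfile",
    "CHPoint",
    "sanitize_sequence",
    "normalized_hydropathy",
    "mean_abs_net_charge",
    "ch_distance",
    "residue_disorder_profile",
    "read_score_track",
    "write_score_track",
]

#: Kyte–Doolittle hydropathy values for the 20 canonical residues.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_CANONICAL = set(KYTE_DOOLITTLE)

#: Residue charges at neutral pH.  Histidine and the termini are treated as 0.
_CHARGE: dict[str, float] = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

#: Default CH boundary R = a·H − b (positive distance = disordered side).
CH_A_DEFAULT = 2.785
CH_B_DEFAULT = 1.151

#: Default sliding-window width for the internal scorer.
SCORER_WINDOW_DEFAULT = 51


def sanitize_sequence(sequence: str, protein_id: str = "?") -> str:
    """Uppercase a sequence and drop non-canonical residues with a warning.

    Ambiguity codes (B, Z, X, J) and rare residues (U, O) have no defined
    Kyte–Doolittle value or neutral-pH charge, so CH statistics are undefined
    for them; they are removed rather than remapped.
    """
    seq = sequence.upper()
    kept = [aa for aa in seq if aa in _CANONICAL]
    n_dropped = len(seq) - len(kept)
    if n_dropped:
        warnings.warn(
            f"{protein_id}: dropped {n_dropped} non-canonical residue(s)",
            stacklevel=2,
        )
    return "".join(kept)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier with its sanitized amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _CANONICAL
        if bad:
            raise ValueError(
                f"{self.id}: non-canonical residues {sorted(bad)}; "
                "pass through sanitize_sequence first"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DisorderProfile:
    """Per-residue disorder scores in [0, 1] for one protein.

    ``source`` records whether scores came from the internal windowed scorer
    (``internal_scorer``) or were read from an external predictor's track
    (``external_track``).
    """

    protein_id: str
    scores: np.ndarray
    source: str = "internal_scorer"
    sequence: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValueError(f"{self.protein_id}: profile must be a non-empty vector")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError(f"{self.protein_id}: scores outside [0, 1]")
        if self.sequence is not None and len(self.sequence) != self.scores.size:
            raise ValueError(f"{self.protein_id}: score length != sequence length")

    def __len__(self) -> int:
        return self.scores.size


@dataclass(frozen=True)
class CHPoint:
    """Charge–hydropathy coordinates and signed boundary distance."""

    hydropathy: float
    abs_net_charge: float
    ch_distance: float


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence.upper()) - _CANONICAL
    if bad:
        raise ValueError(f"non-canonical residues {sorted(bad)}")
    return sequence.upper()


def normalized_hydropathy(sequence: str) -> float:
    """Mean Kyte–Doolittle hydropathy scaled to [0, 1].

    Each residue contributes ``(kd + 4.5) / 9`` so that isoleucine (kd 4.5)
    maps to 1 and arginine (kd −4.5) maps to 0.
    """
    seq = _check_sequence(sequence)
    return float(np.mean([(KYTE_DOOLITTLE[aa] + 4.5) / 9.0 for aa in seq]))


def mean_abs_net_charge(sequence: str) -> float:
    """Absolute net charge per residue: ``|#K + #R − #D − #E| / length``."""
    seq = _check_sequence(sequence)
    net = sum(_CHARGE.get(aa, 0.0) for aa in seq)
    return abs(net) / len(seq)


def ch_distance(
    sequence: str, a: float = CH_A_DEFAULT, b: float = CH_B_DEFAULT
) -> CHPoint:
    """Signed distance of a protein from the CH boundary ``R = a·H − b``.

    Positive values place the protein on the extended-disorder side of the
    boundary, negative values on the compact/ordered side.
    """
    h = normalized_hydropathy(sequence)
    r = mean_abs_net_charge(sequence)
    return CHPoint(hydropathy=h, abs_net_charge=r, ch_distance=r - (a * h - b))


def residue_disorder_profile(
    record: ProteinRecord,
    window: int = SCORER_WINDOW_DEFAULT,
    a: float = CH_A_DEFAULT,
    b: float = CH_B_DEFAULT,
) -> DisorderProfile:
    """FoldIndex-style windowed disorder score for every residue.

    For each position the window (truncated at the sequence ends, never
    padded) yields mean scaled hydropathy ``H_w`` and mean net charge ``R_w``;
    the foldability index is ``FI = a·H_w − |R_w| − b`` and the disorder score
    is ``clamp(0.5 − FI, 0, 1)``.

    Parameters
    ----------
    record : ProteinRecord
        Sanitized query protein.
    window : int
        Odd window width ≥ 5 (default 51).
    """
    if window < 5 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 5, got {window}")
    seq = record.sequence
    n = len(seq)
    hydro = np.array([(KYTE_DOOLITTLE[aa] + 4.5) / 9.0 for aa in seq])
    charge = np.array([_CHARGE.get(aa, 0.0) for aa in seq])
    half = window // 2
    # cumulative sums with leading zero give O(1) truncated-window means
    ch = np.concatenate([[0.0], np.cumsum(hydro)])
    cc = np.concatenate([[0.0], np.cumsum(charge)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    width = hi - lo
    h_w = (ch[hi] - ch[lo]) / width
    r_w = (cc[hi] - cc[lo]) / width
    fi = a * h_w - np.abs(r_w) - b
    scores = np.clip(0.5 - fi, 0.0, 1.0)
    return DisorderProfile(
        protein_id=record.id, scores=scores, source="internal_scorer", sequence=seq
    )


def read_score_track(path, protein_id: str) -> DisorderProfile:
    """Read an externally produced per-residue score track.

    The file is a two-column table: 1-based residue index and a score in
    [0, 1], tab- or whitespace-delimited; ``#`` lines are comments.  Indices
    must be contiguous from 1.
    """
    indices: list[int] = []
    scores: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            try:
                indices.append(int(parts[0]))
                scores.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
    if not indices:
        raise ValueError(f"{path}: empty score track")
    expected = list(range(1, len(indices) + 1))
    if indices != expected:
        raise ValueError(f"{path}: residue indices not contiguous from 1")
    arr = np.asarray(scores)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{path}: scores outside [0, 1]")
    return DisorderProfile(protein_id=protein_id, scores=arr, source="external_track")


def write_score_track(profile: DisorderProfile, path) -> None:
    """Write a profile in the two-column track format read back by
    :func:`read_score_track`."""
    with open(path, "w") as fh:
        fh.write(f"# {profile.protein_id}\n")
        for i, s in enumerate(profile.scores, 1):
            fh.write(f"{i}\t{s:.6f}\n")
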