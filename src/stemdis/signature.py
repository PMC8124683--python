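"""Concordance of a DE profile with direction-annotated resistance signatures.

A drug-resistance signature lists genes with the direction each is expected
to move in resistant cells.  Under the null that the measured profile is
unrelated to the signature, each evaluable gene matches its expected
direction with probability 1/2, so the number of concordant genes is
Binomial(n, 1/2) and the one-sided upper tail P(X ≥ k) scores the evidence
for concordance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import binom

from .de import DEResult

__all__ = [
    "ResistanceSignature",
    "ConcordanceResult",
    "read_signature",
    "write_signature",
    "concordance_test",
]


@dataclass(frozen=True)
class ResistanceSignature:
    """Named gene signature with expected up/down directions."""

    name: str
    entries: tuple[tuple[str, str], ...]  # (gene, expected direction)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"signature {self.name!r} is empty")
        genes = [g for g, _ in self.entries]
        if len(genes) != len(set(genes)):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        bad = {d for _, d in self.entries} - {"up", "down"}
        if bad:
            raise ValueError(f"unknown directions: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ConcordanceResult:
    signature: str
    n_evaluable: int
    n_concordant: int
    p: float


def read_signature(path, name: str | None = None) -> ResistanceSignature:
    """Read a (gene, direction) TSV; '#' lines are comments."""
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected gene<TAB>direction")
            entries.append((parts[0], parts[1]))
    return ResistanceSignature(name=name or str(path), entries=tuple(entries))


def write_signature(signature: ResistanceSignature, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# signature {signature.name}\n")
        for gene, direction in signature.entries:
            fh.write(f"{gene}\t{direction}\n")


def concordance_test(
    signature: ResistanceSignature,
    de: Sequence[DEResult],
    include_ns: bool = False,
) -> ConcordanceResult:
    """One-sided binomial test for direction concordance.

    Evaluable genes are signature genes present in the DE table; with
    ``include_ns=False`` (default) only genes labeled up/down count, and the
    observed direction is the label.  With ``include_ns=True`` every mapped
    gene counts and the observed direction is the sign of its log2FC (zero
    never matches).  p = P(X ≥ n_concordant | n_evaluable, 1/2).
    """
    by_gene = {r.gene: r for r in de}
    n_eval = 0
    n_conc = 0
    for gene, expected in signature.entries:
        r = by_gene.get(gene)
        if r is None:
            continue
        if include_ns:
            observed = "up" if r.log2fc > 0 else ("down" if r.log2fc < 0 else None)
        else:
            observed = r.label if r.label in ("up", "down") else None
            if observed is None:
                continue
        n_eval += 1
        if observed == expected:
            n_conc += 1
    if n_eval == 0:
        raise ValueError(
            f"signature {signature.name!r}: no evaluable genes in the DE table"
        )
    p = float(binom.sf(n_conc - 1, n_eval, 0.5))
    return ConcordanceResult(
        signature=signature.name, n_evaluable=n_eval, n_concordant=n_conc, p=p
    )
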