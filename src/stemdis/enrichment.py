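"""Gene-module enrichment by mean expression with a permutation null.

A module's score is the mean log2 fold change of its member genes present in
the differential-expression table.  Significance is competitive: the null for
a module of m mapped genes is the distribution of mean log2FC over m genes
drawn without replacement from the whole DE table; the two-sided permutation
p-value is ``(1 + #{|null| ≥ |observed|}) / (n_perm + 1)``.  BH-FDR is applied
across the modules of a catalog.

Catalogs (GMT format) are deduplicated first: entries with set-identical gene
membership are united into one entry whose name joins the member names, which
removes the redundancy typical of pathway compendia aggregated from multiple
databases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .de import DEResult

__all__ = [
    "Module",
    "ModuleCatalog",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "dedupe_catalog",
    "module_scores",
    "module_significance",
    "top_modules",
]

logger = logging.getLogger(__name__)

NAME_SEPARATOR = "|"
MIN_GENES_DEFAULT = 5


@dataclass(frozen=True)
class Module:
    name: str
    description: str
    genes: frozenset[str]


@dataclass
class ModuleCatalog:
    modules: list[Module]

    def __len__(self) -> int:
        return len(self.modules)


@dataclass(frozen=True)
class EnrichmentResult:
    """Mean-expression enrichment of one module."""

    module: str
    score: float  # mean log2FC over mapped genes
    n_genes_used: int
    p: float
    q: float
    direction: str  # up | down


def read_gmt(path) -> ModuleCatalog:
    """Read a GMT catalog: name <tab> description <tab> gene ..."""
    modules = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need >= 3 fields")
            modules.append(
                Module(name=parts[0], description=parts[1],
                       genes=frozenset(g for g in parts[2:] if g))
            )
    return ModuleCatalog(modules=modules)


def write_gmt(catalog: ModuleCatalog, path) -> None:
    with open(path, "w") as fh:
        for m in catalog.modules:
            fh.write("\t".join([m.name, m.description, *sorted(m.genes)]) + "\n")


def dedupe_catalog(catalog: ModuleCatalog, separator: str = NAME_SEPARATOR) -> ModuleCatalog:
    """Unite entries with identical gene sets.

    The united entry's name joins the member names (input order, separator
    ``|``); its description is the first member's.  Idempotent.
    """
    by_set: dict[frozenset[str], list[Module]] = {}
    order: list[frozenset[str]] = []
    for m in catalog.modules:
        if m.genes not in by_set:
            by_set[m.genes] = []
            order.append(m.genes)
        by_set[m.genes].append(m)
    united = []
    for gs in order:
        members = by_set[gs]
        name = separator.join(m.name for m in members)
        united.append(Module(name=name, description=members[0].description, genes=gs))
    return ModuleCatalog(modules=united)


def module_scores(
    catalog: ModuleCatalog,
    de: Sequence[DEResult],
    min_genes: int = MIN_GENES_DEFAULT,
) -> dict[str, tuple[float, int]]:
    """Mean log2FC per module over member genes present in the DE table.

    Modules with fewer than ``min_genes`` mapped genes are skipped with a
    logged reason.  Returns module name → (score, n_genes_used).
    """
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    if not catalog.modules:
        raise ValueError("empty catalog")
    fc = {r.gene: r.log2fc for r in de}
    scores: dict[str, tuple[float, int]] = {}
    for m in catalog.modules:
        mapped = [fc[g] for g in m.genes if g in fc]
        if len(mapped) < min_genes:
            logger.info("skipping module %s: %d mapped genes < %d",
                        m.name, len(mapped), min_genes)
            continue
        scores[m.name] = (float(np.mean(mapped)), len(mapped))
    return scores


def module_significance(
    scores: Mapping[str, tuple[float, int]],
    de: Sequence[DEResult],
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Permutation p-values and BH q-values for module scores.

    For each module of m mapped genes, ``n_perm`` null scores are means of m
    log2FC values sampled without replacement from the DE table; the
    two-sided p is ``(1 + #{|null| >= |obs|}) / (n_perm + 1)``.  Deterministic
    for a fixed seed; null draws are shared across modules of equal size.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    fc = np.array([r.log2fc for r in de])
    n_genes = len(fc)
    rng = np.random.default_rng(seed)
    names = sorted(scores)  # seed-stable iteration order
    null_by_size: dict[int, np.ndarray] = {}
    for name in names:
        m = scores[name][1]
        if m not in null_by_size:
            draws = np.empty(n_perm)
            for i in range(n_perm):
                draws[i] = fc[rng.choice(n_genes, size=m, replace=False)].mean()
            null_by_size[m] = np.abs(draws)
    p = np.array(
        [
            (1 + np.count_nonzero(null_by_size[scores[n][1]] >= abs(scores[n][0])))
            / (n_perm + 1)
            for n in names
        ]
    )
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [
        EnrichmentResult(
            module=name,
            score=scores[name][0],
            n_genes_used=scores[name][1],
            p=float(pi),
            q=float(qi),
            direction="up" if scores[name][0] > 0 else "down",
        )
        for name, pi, qi in zip(names, p, q)
    ]


def top_modules(
    results: Sequence[EnrichmentResult], n: int = 60, direction: str = "up"
) -> list[EnrichmentResult]:
    """Top ``n`` modules of a direction: q ascending, then |score| descending,
    then name."""
    if n < 1:
        raise ValueError("n must be >= 1")
    chosen = [r for r in results if r.direction == direction]
    chosen.sort(key=lambda r: (r.q, -abs(r.score), r.module))
    return chosen[:n]


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results]).set_index("module")
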