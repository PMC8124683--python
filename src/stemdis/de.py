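"""Two-group differential expression on a raw count matrix.

Counts are normalized to log2 counts-per-million with a pseudocount,
per-gene significance comes from a two-sided Welch (unequal-variance) t-test
on the normalized values, and multiplicity is controlled with
Benjamini–Hochberg FDR.  Genes are labeled up/down at the configured FDR and
the network stage consumes the subset whose fold change on the normalized
scale is at least the configured ratio (default 10-fold), up- and
down-regulated lists kept separate.

The Welch-on-log-CPM test is a deliberate, fully specified simplification of
moderated-t pipelines: with three replicates per group it is conservative but
has ample power at the large (≥10-fold) effects this pipeline feeds forward.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "read_counts",
    "write_counts",
    "normalize_log_cpm",
    "de_test",
    "filter_fold",
    "de_frame",
]


@dataclass
class ExpressionMatrix:
    """Genes × samples raw counts with a two-group design.

    ``groups`` maps each sample name to ``"case"`` or ``"control"``.
    """

    counts: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene symbols in count matrix")
        if set(self.counts.columns) != set(self.groups):
            raise ValueError("sample names in groups do not match matrix columns")
        bad = set(self.groups.values()) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        for g in ("case", "control"):
            if sum(1 for v in self.groups.values() if v == g) < 2:
                raise ValueError(f"fewer than 2 replicates in group {g!r}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential-expression summary."""

    gene: str
    log2fc: float
    p: float
    q: float
    label: str  # up | down | ns


def read_counts(path, group_map: dict[str, str]) -> ExpressionMatrix:
    """Read a gene × sample TSV (header row, first column gene symbols)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(counts=df, groups=dict(group_map))


def write_counts(matrix: ExpressionMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t")


def normalize_log_cpm(matrix: ExpressionMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million: ``log2((c + pc) / (libsize + 2·pc) · 1e6)``."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    counts = matrix.counts.astype(float)
    if counts.empty:
        raise ValueError("empty count matrix")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return np.log2((counts + pseudocount) / (lib + 2 * pseudocount) * 1e6)


def de_test(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> list[DEResult]:
    """Welch t-test per gene on log-CPM values with BH-FDR labels.

    ``log2fc`` is mean(case) − mean(control) on the normalized scale.  Genes
    with zero variance in both groups receive p = 1 (deterministic degenerate
    handling).  Labels: up if q < alpha and log2fc > 0, down if q < alpha and
    log2fc < 0, else ns.
    """
    logcpm = normalize_log_cpm(matrix, pseudocount)
    case = logcpm[matrix.samples_in("case")].to_numpy()
    ctrl = logcpm[matrix.samples_in("control")].to_numpy()
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    zero_var = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    results = []
    for gene, fc, pi, qi in zip(matrix.counts.index, log2fc, p, q):
        if qi < alpha and fc > 0:
            label = "up"
        elif qi < alpha and fc < 0:
            label = "down"
        else:
            label = "ns"
        results.append(DEResult(gene=str(gene), log2fc=float(fc), p=float(pi),
                                q=float(qi), label=label))
    return results


def filter_fold(
    results: Sequence[DEResult], min_fold: float = 10.0
) -> tuple[list[str], list[str]]:
    """Significant genes changed at least ``min_fold``-fold, split by direction.

    Returns ``(up_genes, down_genes)``; a gene qualifies when its label is not
    ns and ``|log2fc| ≥ log2(min_fold)``.
    """
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    cut = np.log2(min_fold)
    up = [r.gene for r in results if r.label == "up" and r.log2fc >= cut]
    down = [r.gene for r in results if r.label == "down" and -r.log2fc >= cut]
    return up, down


def de_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    """Results as a DataFrame (gene, log2fc, p, q, label) for TSV export."""
    return pd.DataFrame([asdict(r) for r in results]).set_index("gene")
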