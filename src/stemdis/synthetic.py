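"""Synthetic inputs with planted ground truth for every pipeline stage.

The study design this package targets — a reporter-enriched cancer stem-like
line against its parental line, three biological replicates each — has no
deposited raw data, so each stage is exercised on generated inputs whose
truth is known by construction:

* protein cohorts whose residue composition is drawn predominantly from
  order-promoting (W, C, F, I, Y, V, L, N) or disorder-promoting
  (A, R, G, Q, S, P, E, K) residues, so any composition-sensitive disorder
  scorer can recover the planted labels;
* negative-binomial RNA-seq counts with planted up/down genes at a stated
  fold change, library sizes jittered log-normally within ±20% of a target
  depth;
* interaction networks with planted dense communities, cross-community noise
  edges, and designated hub nodes wired to more than five within-community
  partners;
* GMT module catalogs with a controlled fraction of exact-duplicate entries;
* direction-annotated signatures whose genes are concordant with the
  expected direction independently with a stated probability.

Every generator takes a single integer seed; independent substreams are
split from it with ``numpy.random.SeedSequence.spawn``, and equal seeds give
byte-identical output files.  Each generator returns its artifact together
with a truth table (``entity_id``, ``planted_label``, ``planted_effect``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ORDER_PROMOTING",
    "DISORDER_PROMOTING",
    "gen_protein_cohort",
    "gen_expression",
    "gen_interaction_network",
    "gen_module_catalog",
    "gen_signature",
    "write_truth",
    "read_truth",
]

ORDER_PROMOTING = tuple("WCFIYVLN")
DISORDER_PROMOTING = tuple("ARGQSPEK")
_ALL_AA = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Probability a residue is drawn from the designated composition set
#: (remainder uniform over all 20), strong enough that planted labels are
#: recoverable by any composition-sensitive scorer.
_COMPOSITION_BIAS = 0.9


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    # keep_default_na so the label "null" survives as a string
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def _sample_sequence(rng: np.random.Generator, length: int, favored: tuple[str, ...]) -> str:
    from_set = rng.random(length) < _COMPOSITION_BIAS
    core = rng.choice(len(favored), size=length)
    anyaa = rng.choice(len(_ALL_AA), size=length)
    return "".join(
        favored[c] if f else _ALL_AA[a] for f, c, a in zip(from_set, core, anyaa)
    )


def gen_protein_cohort(
    n_ordered: int,
    n_disordered: int,
    length_range: tuple[int, int] = (80, 300),
    seed: int = 0,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Generate a protein cohort with composition-planted disorder labels.

    Returns Biopython records (ids ``ORD_0001`` / ``DIS_0001`` …) and a truth
    table with planted labels ``ordered`` / ``disordered``.
    """
    if n_ordered < 0 or n_disordered < 0:
        raise ValueError("counts must be >= 0")
    lo, hi = length_range
    if not (10 <= lo <= hi):
        raise ValueError(f"invalid length range {length_range}")
    (rng,) = _streams(seed, 1)
    records: list[SeqRecord] = []
    rows = []
    for label, prefix, count, favored in (
        ("ordered", "ORD", n_ordered, ORDER_PROMOTING),
        ("disordered", "DIS", n_disordered, DISORDER_PROMOTING),
    ):
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            seq = _sample_sequence(rng, length, favored)
            pid = f"{prefix}_{i + 1:04d}"
            records.append(SeqRecord(Seq(seq), id=pid, description=""))
            rows.append({"entity_id": pid, "planted_label": label,
                         "planted_effect": float("nan")})
    truth = pd.DataFrame(rows, columns=["entity_id", "planted_label", "planted_effect"])
    return records, truth


def write_fasta(records: list[SeqRecord], path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    SeqIO.write(records, path, "fasta")


def gen_expression(
    n_genes: int,
    n_up: int,
    n_down: int,
    fold: float = 16.0,
    dispersion: float = 0.1,
    reps_per_group: int = 3,
    seed: int = 0,
    target_depth: float = 1e6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with planted differential genes.

    Genes ``G0001 …``; samples ``case_1 … case_r, control_1 … control_r``.
    The first ``n_up`` genes have case mean multiplied by ``fold``, the next
    ``n_down`` divided by it; the rest are null.  Per-gene base means are
    log-normal; per-sample library-size factors are log-normal, clipped to
    ±20% of the target depth.  Counts are NB with variance ``µ + φµ²``.
    """
    if n_up + n_down > n_genes:
        raise ValueError("planted gene count exceeds n_genes")
    if fold < 1:
        raise ValueError("fold must be >= 1")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if reps_per_group < 2:
        raise ValueError("need >= 2 replicates per group")
    rng_base, rng_lib, rng_counts = _streams(seed, 3)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    base = rng_base.lognormal(mean=math.log(100.0), sigma=1.0, size=n_genes)
    effect = np.ones(n_genes)
    effect[:n_up] = fold
    effect[n_up : n_up + n_down] = 1.0 / fold
    lib = np.clip(
        rng_lib.lognormal(mean=0.0, sigma=0.1, size=2 * reps_per_group), 0.8, 1.2
    )
    lib *= target_depth / (base.sum() or 1.0)
    samples = [f"case_{j + 1}" for j in range(reps_per_group)] + [
        f"control_{j + 1}" for j in range(reps_per_group)
    ]
    counts = np.empty((n_genes, 2 * reps_per_group), dtype=np.int64)
    inv_phi = 1.0 / dispersion
    for j in range(2 * reps_per_group):
        mu = base * (effect if j < reps_per_group else 1.0) * lib[j]
        p = inv_phi / (inv_phi + mu)
        counts[:, j] = rng_counts.negative_binomial(inv_phi, p)
    matrix = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    if fold == 1.0:  # no effect ⇒ nothing is truly differential
        labels = ["null"] * n_genes
        effects = [0.0] * n_genes
    else:
        labels = ["up"] * n_up + ["down"] * n_down + ["null"] * (n_genes - n_up - n_down)
        effects = [math.log2(fold)] * n_up + [-math.log2(fold)] * n_down + [0.0] * (
            n_genes - n_up - n_down
        )
    truth = pd.DataFrame(
        {"entity_id": genes, "planted_label": labels, "planted_effect": effects}
    )
    return matrix, truth


def gen_interaction_network(
    nodes: list[str],
    n_clusters: int = 3,
    p_intra: float = 0.6,
    p_inter: float = 0.02,
    hub_nodes: list[str] | None = None,
    confidence_params: tuple[float, float] = (0.95, 0.5),
    seed: int = 0,
) -> tuple[list[tuple[str, str, float]], pd.DataFrame]:
    """Planted-partition network with designated hubs and scored edges.

    Nodes are split round-robin into ``n_clusters`` communities.  Edges within
    a community appear with ``p_intra`` and carry confidence near
    ``mean_true``; cross-community edges appear with ``p_inter`` at
    ``mean_false``.  Each hub node is additionally wired to more than five
    within-community partners at ``mean_true``.  Truth records each node's
    community index and hub flag (``cluster<k>`` / ``cluster<k>:hub``).
    """
    if not 0 <= p_inter < p_intra <= 1:
        raise ValueError("need 0 <= p_inter < p_intra <= 1")
    mean_true, mean_false = confidence_params
    if not (0 <= mean_true <= 1 and 0 <= mean_false <= 1):
        raise ValueError("confidence means must be in [0, 1]")
    hub_nodes = list(hub_nodes or [])
    unknown = set(hub_nodes) - set(nodes)
    if unknown:
        raise ValueError(f"hub nodes not in node list: {sorted(unknown)}")
    membership = {v: i % n_clusters for i, v in enumerate(nodes)}
    by_cluster: dict[int, list[str]] = {}
    for v, c in membership.items():
        by_cluster.setdefault(c, []).append(v)
    for h in hub_nodes:
        if len(by_cluster[membership[h]]) <= 6:
            raise ValueError(
                f"hub {h!r} infeasible: community has "
                f"{len(by_cluster[membership[h]])} nodes, need > 6"
            )
    rng_topo, rng_conf = _streams(seed, 2)

    def conf(mean: float) -> float:
        return float(np.clip(rng_conf.normal(mean, 0.02), 0.0, 1.0))

    edges: dict[tuple[str, str], float] = {}
    ordered = sorted(nodes)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            same = membership[a] == membership[b]
            if rng_topo.random() < (p_intra if same else p_inter):
                edges[(a, b)] = conf(mean_true if same else mean_false)
    for h in hub_nodes:
        partners = [v for v in by_cluster[membership[h]] if v != h]
        want = rng_topo.choice(len(partners), size=min(6, len(partners)), replace=False)
        for w in want:
            key = tuple(sorted((h, partners[int(w)])))
            edges.setdefault(key, conf(mean_true))
    edge_list = [(a, b, c) for (a, b), c in sorted(edges.items())]
    hub_set = set(hub_nodes)
    truth = pd.DataFrame(
        {
            "entity_id": list(nodes),
            "planted_label": [
                f"cluster{membership[v]}" + (":hub" if v in hub_set else "")
                for v in nodes
            ],
            "planted_effect": [float(membership[v]) for v in nodes],
        }
    )
    return edge_list, truth


def gen_module_catalog(
    universe: list[str],
    n_modules: int = 20,
    module_size_range: tuple[int, int] = (10, 30),
    planted_modules: list[tuple[list[str], str]] | None = None,
    duplicate_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str, list[str]]], pd.DataFrame]:
    """GMT-style catalog of random modules plus planted ones, with exact
    duplicates.

    Of ``n_modules`` entries, ``round(duplicate_fraction · n_modules)`` are
    byte-identical gene-set copies of earlier entries under different names.
    Planted modules (gene list, direction) are prepended and never
    duplicated away.  Returns rows ``(name, description, genes)`` and truth
    labels ``planted_up`` / ``planted_down`` / ``random`` / ``duplicate``.
    """
    if not 0 <= duplicate_fraction < 1:
        raise ValueError("duplicate_fraction must be in [0, 1)")
    lo, hi = module_size_range
    if hi > len(universe):
        raise ValueError("module size exceeds gene universe")
    (rng,) = _streams(seed, 1)
    rows: list[tuple[str, str, list[str]]] = []
    truth_rows = []
    for i, (genes, direction) in enumerate(planted_modules or []):
        name = f"PLANTED_{direction.upper()}_{i + 1}"
        rows.append((name, f"planted {direction} module", sorted(genes)))
        truth_rows.append({"entity_id": name, "planted_label": f"planted_{direction}",
                           "planted_effect": float("nan")})
    n_dup = round(duplicate_fraction * n_modules)
    n_random = n_modules - n_dup
    if n_random < 1:
        raise ValueError("duplicate_fraction leaves no unique modules")
    for i in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(universe), size=size, replace=False)
        genes = sorted(universe[int(j)] for j in idx)
        name = f"MOD_{i + 1:03d}"
        rows.append((name, "random module", genes))
        truth_rows.append({"entity_id": name, "planted_label": "random",
                           "planted_effect": float("nan")})
    originals = rows[len(planted_modules or []):]
    for i in range(n_dup):
        src = originals[int(rng.integers(0, n_random))]
        name = f"DUP_{i + 1:03d}"
        rows.append((name, src[1], list(src[2])))
        truth_rows.append({"entity_id": name, "planted_label": "duplicate",
                           "planted_effect": float("nan")})
    truth = pd.DataFrame(truth_rows,
                         columns=["entity_id", "planted_label", "planted_effect"])
    return rows, truth


def write_gmt_rows(rows: list[tuple[str, str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, desc, genes in rows:
            fh.write("\t".join([name, desc, *genes]) + "\n")


def gen_signature(
    n_genes: int,
    concordant_fraction: float = 1.0,
    seed: int = 0,
    gene_prefix: str = "SIG",
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Direction-annotated signature with controlled concordance.

    Each gene gets a random expected direction; independently with
    probability ``concordant_fraction`` its planted DE direction matches the
    expectation, otherwise it opposes it.  Truth carries the concordance flag
    and the planted log2FC (±2, signed by the planted DE direction) from
    which a matching DE table can be constructed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= concordant_fraction <= 1:
        raise ValueError("concordant_fraction must be in [0, 1]")
    (rng,) = _streams(seed, 1)
    entries = []
    truth_rows = []
    for i in range(n_genes):
        gene = f"{gene_prefix}_{i + 1:04d}"
        expected = "up" if rng.random() < 0.5 else "down"
        concordant = bool(rng.random() < concordant_fraction)
        observed = expected if concordant else ("down" if expected == "up" else "up")
        entries.append((gene, expected))
        truth_rows.append(
            {
                "entity_id": gene,
                "planted_label": "concordant" if concordant else "discordant",
                "planted_effect": 2.0 if observed == "up" else -2.0,
            }
        )
    truth = pd.DataFrame(truth_rows,
                         columns=["entity_id", "planted_label", "planted_effect"])
    return entries, truth
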