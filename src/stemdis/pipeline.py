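"""End-to-end orchestration: simulate → DE → network → modules → signature →
disorder → combined JSON study report.

Every stage writes its outputs as plain files under the configured output
directory and the merged report embeds the tool version, the effective
configuration, its hash, and SHA-256 checksums of all consumed inputs, so a
rerun with the same seed into a clean directory reproduces identical
artifacts byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import classify, de, enrichment, network, signature, synthetic
from .config import StudyConfig
from .disorder import ProteinRecord, residue_disorder_profile

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger("stemdis.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("[%s] start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("expression")
def _get_expression(cfg: StudyConfig, outdir: Path, checksums: dict):
    if cfg.inputs.counts:
        matrix = de.read_counts(cfg.inputs.counts, cfg.inputs.groups)
        checksums[str(cfg.inputs.counts)] = _sha256(Path(cfg.inputs.counts))
        return matrix, None
    if not cfg.simulate.enabled:
        raise ValueError("no counts file configured and simulation disabled")
    s = cfg.simulate.expression
    counts, truth = synthetic.gen_expression(
        s.n_genes, s.n_up, s.n_down, s.fold, s.dispersion, s.reps_per_group,
        seed=cfg.seed,
    )
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    synthetic.write_truth(truth, outdir / "expression_truth.tsv")
    groups = {c: ("case" if c.startswith("case") else "control")
              for c in counts.columns}
    return de.ExpressionMatrix(counts=counts, groups=groups), truth


@_stage("de")
def _run_de(cfg: StudyConfig, matrix, outdir: Path):
    results = de.de_test(matrix, alpha=cfg.de.alpha, pseudocount=cfg.de.pseudocount)
    frame = de.de_frame(results)
    frame.to_csv(outdir / "de.tsv", sep="\t")
    volcano = pd.DataFrame(
        {
            "log2fc": frame["log2fc"],
            "neg_log10_q": -np.log10(frame["q"].clip(lower=1e-300)),
            "label": frame["label"],
        }
    )
    volcano.to_csv(outdir / "volcano.tsv", sep="\t")
    up, down = de.filter_fold(results, cfg.de.min_fold)
    (outdir / "genes_up.txt").write_text("\n".join(up) + ("\n" if up else ""))
    (outdir / "genes_down.txt").write_text("\n".join(down) + ("\n" if down else ""))
    return results, up, down


def _analyze_gene_list(cfg: StudyConfig, genes, edges, seed):
    g = network.build_network(edges, genes, cfg.network.min_confidence)
    comp = network.largest_component(g)
    hub_list = network.hubs(comp, cfg.network.min_links)
    k = min(cfg.network.k, max(comp.number_of_nodes(), 1))
    clusters = network.cluster(comp, k, seed=seed) if comp.number_of_nodes() else {}
    payload = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "largest_component_size": comp.number_of_nodes(),
        "hubs": hub_list,
        "clusters": clusters,
    }
    return payload, clusters


@_stage("network")
def _run_network(cfg: StudyConfig, up: list[str], down: list[str],
                 outdir: Path, checksums: dict):
    """Up- and down-regulated gene lists are analyzed separately.

    With external edges both lists run against the same edge file.  In
    simulate mode a planted-community network is generated per direction;
    a direction whose gene list is too small to host the planted communities
    is reported as skipped rather than aborting the run.
    """
    payloads: dict[str, dict] = {}
    clusters_by_dir: dict[str, dict] = {}
    truths: dict[str, object] = {}
    external = bool(cfg.inputs.edges)
    if external:
        shared_edges = network.read_edges(cfg.inputs.edges)
        checksums[str(cfg.inputs.edges)] = _sha256(Path(cfg.inputs.edges))
    s = cfg.simulate.network
    for direction, genes, seed in (("up", up, cfg.seed + 1),
                                   ("down", down, cfg.seed + 11)):
        if external:
            edges = shared_edges
            truths[direction] = None
        else:
            if len(genes) < 7 * s.n_clusters:
                logger.info("network[%s]: only %d genes, skipping",
                            direction, len(genes))
                payloads[direction] = {
                    "skipped": f"{len(genes)} genes < {7 * s.n_clusters} needed"
                }
                continue
            nodes = sorted(genes)
            edges, net_truth = synthetic.gen_interaction_network(
                nodes,
                n_clusters=s.n_clusters,
                p_intra=s.p_intra,
                p_inter=s.p_inter,
                hub_nodes=nodes[: s.n_hubs],
                confidence_params=(s.confidence_true, s.confidence_false),
                seed=seed,
            )
            network.write_edges(edges, outdir / f"edges_{direction}.tsv")
            synthetic.write_truth(net_truth, outdir / f"network_truth_{direction}.tsv")
            truths[direction] = net_truth
        payload, clusters = _analyze_gene_list(cfg, genes, edges, cfg.seed)
        payloads[direction] = payload
        clusters_by_dir[direction] = clusters
        for cid in sorted(set(clusters.values())):
            members = sorted(v for v, c in clusters.items() if c == cid)
            (outdir / f"cluster_{direction}_{cid}.txt").write_text(
                "\n".join(members) + "\n"
            )
    (outdir / "network.json").write_text(
        json.dumps(payloads, indent=2, sort_keys=True)
    )
    return payloads, clusters_by_dir, truths


@_stage("modules")
def _run_modules(cfg: StudyConfig, de_results, outdir: Path, checksums: dict):
    if cfg.inputs.gmt:
        catalog = enrichment.read_gmt(cfg.inputs.gmt)
        checksums[str(cfg.inputs.gmt)] = _sha256(Path(cfg.inputs.gmt))
    else:
        s = cfg.simulate.catalog
        universe = [r.gene for r in de_results]
        up_genes = [r.gene for r in de_results if r.label == "up"]
        down_genes = [r.gene for r in de_results if r.label == "down"]
        planted = []
        if len(up_genes) >= s.planted_size:
            planted.append((up_genes[: s.planted_size], "up"))
        if len(down_genes) >= s.planted_size:
            planted.append((down_genes[: s.planted_size], "down"))
        rows, _ = synthetic.gen_module_catalog(
            universe,
            n_modules=s.n_modules,
            module_size_range=(s.size_min, s.size_max),
            planted_modules=planted[: s.n_planted],
            duplicate_fraction=s.duplicate_fraction,
            seed=cfg.seed + 2,
        )
        synthetic.write_gmt_rows(rows, outdir / "catalog.gmt")
        catalog = enrichment.read_gmt(outdir / "catalog.gmt")
    deduped = enrichment.dedupe_catalog(catalog)
    scores = enrichment.module_scores(deduped, de_results, cfg.modules.min_genes)
    results = enrichment.module_significance(
        scores, de_results, n_perm=cfg.modules.n_perm, seed=cfg.seed + 3
    )
    enrichment.enrichment_frame(results).to_csv(outdir / "modules.tsv", sep="\t")
    top = {
        d: [r.module for r in enrichment.top_modules(results, cfg.modules.top_n, d)]
        for d in ("up", "down")
    }
    return results, top


@_stage("signature")
def _run_signature(cfg: StudyConfig, de_results, outdir: Path, checksums: dict):
    if cfg.inputs.signature:
        sig = signature.read_signature(cfg.inputs.signature)
        checksums[str(cfg.inputs.signature)] = _sha256(Path(cfg.inputs.signature))
    else:
        s = cfg.simulate.signature
        labeled = [r for r in de_results if r.label in ("up", "down")]
        if len(labeled) < s.n_genes:
            raise ValueError("too few significant genes to build a signature")
        rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed + 4).generate_state(1)[0]
        )
        picks = rng.choice(len(labeled), size=s.n_genes, replace=False)
        entries = []
        for i in picks:
            r = labeled[int(i)]
            concordant = rng.random() < s.concordant_fraction
            expected = r.label if concordant else ("down" if r.label == "up" else "up")
            entries.append((r.gene, expected))
        sig = signature.ResistanceSignature(name="simulated", entries=tuple(entries))
        signature.write_signature(sig, outdir / "signature.tsv")
    result = signature.concordance_test(sig, de_results)
    return result


@_stage("disorder")
def _run_disorder(cfg: StudyConfig, outdir: Path, checksums: dict):
    cohorts = {}
    if cfg.inputs.fasta_induced or cfg.inputs.fasta_inhibited:
        from Bio import SeqIO

        from .disorder import sanitize_sequence

        for name, path in (("induced", cfg.inputs.fasta_induced),
                           ("inhibited", cfg.inputs.fasta_inhibited)):
            if not path:
                continue
            checksums[str(path)] = _sha256(Path(path))
            records = [
                ProteinRecord(r.id, sanitize_sequence(str(r.seq), r.id))
                for r in SeqIO.parse(path, "fasta")
            ]
            cohorts[name] = records
    else:
        s = cfg.simulate.proteins
        for name, offset in (("induced", 5), ("inhibited", 6)):
            records, truth = synthetic.gen_protein_cohort(
                s.n_ordered, s.n_disordered, (s.length_min, s.length_max),
                seed=cfg.seed + offset,
            )
            synthetic.write_fasta(records, outdir / f"proteins_{name}.fasta")
            synthetic.write_truth(truth, outdir / f"proteins_{name}_truth.tsv")
            cohorts[name] = [ProteinRecord(r.id, str(r.seq)) for r in records]
    reports = {}
    for name, records in cohorts.items():
        summaries = [
            classify.summarize_protein(
                rec, window=cfg.disorder.window,
                ch_a=cfg.disorder.ch_a, ch_b=cfg.disorder.ch_b,
            )
            for rec in records
        ]
        pd.DataFrame([s.to_dict() for s in summaries]).to_csv(
            outdir / f"disorder_{name}.tsv", sep="\t", index=False
        )
        reports[name] = classify.cohort_summary(summaries, name).to_dict()
    return reports


def run_pipeline(cfg: StudyConfig) -> dict:
    """Run every stage and return (and write) the merged study report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}

    matrix, expr_truth = _get_expression(cfg, outdir, checksums)
    de_results, up, down = _run_de(cfg, matrix, outdir)
    net_payload, clusters_by_dir, net_truths = _run_network(
        cfg, up, down, outdir, checksums
    )
    module_results, top = _run_modules(cfg, de_results, outdir, checksums)
    sig_result = _run_signature(cfg, de_results, outdir, checksums)
    disorder_reports = _run_disorder(cfg, outdir, checksums)

    report = {
        "tool": "stemdis",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "input_checksums": checksums,
        "de": {
            "n_genes": len(de_results),
            "n_up": sum(1 for r in de_results if r.label == "up"),
            "n_down": sum(1 for r in de_results if r.label == "down"),
            "n_up_min_fold": len(up),
            "n_down_min_fold": len(down),
        },
        "network": net_payload,
        "modules": {
            "n_tested": len(module_results),
            "n_significant": sum(1 for r in module_results if r.q < cfg.de.alpha),
            "top": top,
        },
        "signature": {
            "name": sig_result.signature,
            "n_evaluable": sig_result.n_evaluable,
            "n_concordant": sig_result.n_concordant,
            "p": sig_result.p,
        },
        "disorder": disorder_reports,
    }

    if expr_truth is not None:
        planted = expr_truth[expr_truth.planted_label.isin(["up", "down"])]
        by_gene = {r.gene: r.label for r in de_results}
        hits = sum(
            1 for _, row in planted.iterrows()
            if by_gene.get(row.entity_id) == row.planted_label
        )
        report["recovery"] = {
            "de_direction_recovery": hits / len(planted) if len(planted) else None,
        }
    for direction, net_truth in net_truths.items():
        clusters = clusters_by_dir.get(direction)
        if net_truth is None or not clusters:
            continue
        from sklearn.metrics import adjusted_rand_score

        truth_map = dict(zip(net_truth.entity_id, net_truth.planted_effect))
        common = sorted(set(clusters) & set(truth_map))
        if common:
            report.setdefault("recovery", {})[f"network_ari_{direction}"] = float(
                adjusted_rand_score(
                    [truth_map[v] for v in common], [clusters[v] for v in common]
                )
            )

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
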