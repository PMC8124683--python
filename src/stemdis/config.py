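"""Declarative study configuration for the end-to-end pipeline.

Defaults follow the analysis conventions the pipeline mirrors: interaction
confidence floor 0.9 (strict), hub threshold of more than five links,
10-fold expression gate for the network stage, residue-score thresholds
0.5 / 0.25 / 0.15, and PPIDR 10% / 30% plus MDS 0.25 / 0.5 protein bins
(the bin cuts are fixed in :mod:`stemdis.classify`).  Every block is a plain
dataclass so a run's effective configuration serializes verbatim into its
report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["StudyConfig", "load_config"]


@dataclass
class SimulateExpression:
    n_genes: int = 2000
    n_up: int = 100
    n_down: int = 100
    fold: float = 16.0
    dispersion: float = 0.1
    reps_per_group: int = 3


@dataclass
class SimulateNetwork:
    """Planted-community network emulating a high-confidence STRING export:
    cross-community noise edges also score above the 0.9 floor, so the
    clustering stage sees a connected graph and must separate communities by
    topology rather than by the confidence filter alone."""

    n_clusters: int = 3
    p_intra: float = 0.6
    p_inter: float = 0.02
    n_hubs: int = 2
    confidence_true: float = 0.95
    confidence_false: float = 0.92


@dataclass
class SimulateCatalog:
    n_modules: int = 40
    size_min: int = 10
    size_max: int = 30
    duplicate_fraction: float = 0.1
    n_planted: int = 2
    planted_size: int = 20


@dataclass
class SimulateSignature:
    n_genes: int = 30
    concordant_fraction: float = 0.9


@dataclass
class SimulateProteins:
    n_ordered: int = 50
    n_disordered: int = 50
    length_min: int = 80
    length_max: int = 300


@dataclass
class SimulateBlock:
    enabled: bool = True
    expression: SimulateExpression = field(default_factory=SimulateExpression)
    network: SimulateNetwork = field(default_factory=SimulateNetwork)
    catalog: SimulateCatalog = field(default_factory=SimulateCatalog)
    signature: SimulateSignature = field(default_factory=SimulateSignature)
    proteins: SimulateProteins = field(default_factory=SimulateProteins)


@dataclass
class InputsBlock:
    """External input files, used when simulation is disabled."""

    counts: str | None = None
    groups: dict[str, str] = field(default_factory=dict)
    edges: str | None = None
    gmt: str | None = None
    signature: str | None = None
    fasta_induced: str | None = None
    fasta_inhibited: str | None = None


@dataclass
class DEBlock:
    alpha: float = 0.05
    pseudocount: float = 0.5
    min_fold: float = 10.0


@dataclass
class NetworkBlock:
    min_confidence: float = 0.9
    min_links: int = 5
    k: int = 3


@dataclass
class ModulesBlock:
    n_perm: int = 2000
    min_genes: int = 5
    top_n: int = 60


@dataclass
class DisorderBlock:
    window: int = 51
    ch_a: float = 2.785
    ch_b: float = 1.151


@dataclass
class StudyConfig:
    seed: int = 0
    outdir: str = "stemdis_run"
    simulate: SimulateBlock = field(default_factory=SimulateBlock)
    inputs: InputsBlock = field(default_factory=InputsBlock)
    de: DEBlock = field(default_factory=DEBlock)
    network: NetworkBlock = field(default_factory=NetworkBlock)
    modules: ModulesBlock = field(default_factory=ModulesBlock)
    disorder: DisorderBlock = field(default_factory=DisorderBlock)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _build(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in _NESTED.get(cls, {}):
            value = _build(_NESTED[cls][f.name], value)
        kwargs[f.name] = value
    unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**kwargs)


_NESTED = {
    StudyConfig: {
        "simulate": SimulateBlock,
        "inputs": InputsBlock,
        "de": DEBlock,
        "network": NetworkBlock,
        "modules": ModulesBlock,
        "disorder": DisorderBlock,
    },
    SimulateBlock: {
        "expression": SimulateExpression,
        "network": SimulateNetwork,
        "catalog": SimulateCatalog,
        "signature": SimulateSignature,
        "proteins": SimulateProteins,
    },
}


def load_config(path) -> StudyConfig:
    """Load a YAML study configuration; missing keys take defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(StudyConfig, data)
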