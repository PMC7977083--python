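"""Pipeline configuration: every numeric constant of the workflow lives here.

Defaults: QC keeps cells with >= 2000 detected genes and low glial
contamination; clustering selects the top 6000 Fano-factor genes, builds
modules at power 1 / cutheight 0.995, splits cells by Ward linkage on
eigengene correlation, merges cluster pairs whose summed capped
-log10 p DE score falls below 100; the consensus stage runs 100
bootstrap iterations on 80% subsamples and merges clusters with mean
co-clustering above 0.25; DE uses FDR 0.05 and |log2FC| >= 1; minor
clusters are those under 15 cells.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .modules import ModuleParams


@dataclass(frozen=True)
class QCConfig:
    min_genes: int = 2000
    contamination_dialect: str = "methods"  # or "main_text"
    contaminant_genes: tuple[str, ...] = ("Apoe", "Mpz", "Mbp")


@dataclass(frozen=True)
class DEConfig:
    d0: float = 4.0
    fdr: float = 0.05
    lfc: float = 1.0
    score_cap: float = 20.0


@dataclass(frozen=True)
class ClusteringConfig:
    n_top_genes: int = 6000
    module: ModuleParams = field(default_factory=ModuleParams)
    n_perm: int = 100
    alpha: float = 0.05
    k_max: int = 4
    min_cluster_size: int = 4
    merge_threshold: float = 100.0
    de: DEConfig = field(default_factory=DEConfig)
    minor_size_threshold: int = 15


@dataclass(frozen=True)
class ConsensusConfig:
    n_iter: int = 100
    frac: float = 0.8
    coclust_threshold: float = 0.25


@dataclass(frozen=True)
class MarkerConfig:
    tau_on: float = 0.7
    tau_off: float = 0.2
    min_pairs: int = 2
    exclude_minor: bool = True


@dataclass(frozen=True)
class EmbeddingConfig:
    n_pcs: int = 20
    perplexity: float = 30.0


@dataclass(frozen=True)
class PipelineConfig:
    qc: QCConfig = field(default_factory=QCConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    markers: MarkerConfig = field(default_factory=MarkerConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        qc = d.get("qc", {})
        if "contaminant_genes" in qc:
            qc = {**qc, "contaminant_genes": tuple(qc["contaminant_genes"])}
        clustering = dict(d.get("clustering", {}))
        if "module" in clustering:
            clustering["module"] = ModuleParams(**clustering["module"])
        if "de" in clustering:
            clustering["de"] = DEConfig(**clustering["de"])
        return cls(
            qc=QCConfig(**qc),
            clustering=ClusteringConfig(**clustering),
            consensus=ConsensusConfig(**d.get("consensus", {})),
            markers=MarkerConfig(**d.get("markers", {})),
            embedding=EmbeddingConfig(**d.get("embedding", {})),
            seed=int(d.get("seed", 0)),
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2, default=str)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
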