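"""Pipeline configuration: nested, validated, with defaults fixed to the
analysis conventions the package implements (k = 40 mutual neighbors, 20
PCs, 3000 HVGs, 1000-feature / 1% Mt nucleus QC, 30-node component pruning,
FC 1.5 / FDR 0.05 differential expression, 5-unit peak windows).

Unknown keys are rejected so a typo in a YAML file fails loudly instead of
silently running with defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

CONFIG_VERSION = "1"


@dataclass
class SimulateConfig:
    enabled: bool = True
    n_genes: int = 2000
    n_tf: int = 200
    frac_off_switch: float = 0.62
    cohort_ages: list[float] = field(default_factory=lambda: [1, 2, 4, 8])
    n_per_cohort: int = 600
    doublet_rate: float = 0.04
    lowq_rate: float = 0.03
    mito_boost: float = 8.0
    clustered: bool = False   # discrete 10-cluster layout instead of continuum


@dataclass
class QCConfig:
    min_features: int = 1000
    max_mito: float = 0.01
    mv_z_cut: float = 3.0
    use_mv_outlier: bool = True
    doublet_k: int = 20
    doublet_threshold_mult: float = 2.0
    feature_min_total: int = 20
    feature_min_frac: float = 0.01
    feature_max_frac: float = 0.80
    blacklist: list[str] | None = None   # None -> shipped default list
    n_hvgs: int = 3000
    quick_k: int = 10
    quick_min_cluster: int = 50


@dataclass
class ClusterConfig:
    d: int = 20
    k: int = 40
    min_component: int = 30
    resolution: float = 1.0
    refine_min_degs: int = 5
    fc: float = 1.5
    fdr: float = 0.05
    top_markers: int = 10


@dataclass
class IntegrateConfig:
    enabled: bool = False
    k: int = 20
    min_conf: float = 0.5
    min_label_n: int = 10
    query_cohort_ages: list[float] = field(default_factory=lambda: [2, 3, 4, 5, 8])
    query_n_per_cohort: int = 300


@dataclass
class TrajectoryConfig:
    root_cluster: str = "RGL"
    curve_dim: int = 3
    ventral_z_cut: float = 2.0
    ventral_genes: list[str] = field(default_factory=list)
    min_prominence: float = 0.05
    window: float = 5.0
    span: float = 0.2
    max_iter: int = 50
    tol: float = 1e-3


@dataclass
class TFConfig:
    tf_list: str | None = None   # path to a TF universe file; None -> truth
    df_smooth: int = 4
    fdr: float = 0.05
    on_frac: float = 0.25
    off_frac: float = 0.10


@dataclass
class RegulonConfig:
    gmt: str | None = None       # path to regulons; None -> planted truth
    top_fraction: float = 0.05
    n_top_targets: int = 50
    min_size: int = 10


@dataclass
class PipelineConfig:
    seed: int = 0
    version: str = CONFIG_VERSION
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    integrate: IntegrateConfig = field(default_factory=IntegrateConfig)
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    tf: TFConfig = field(default_factory=TFConfig)
    regulons: RegulonConfig = field(default_factory=RegulonConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def section_dict(self, name: str) -> dict:
        return dataclasses.asdict(getattr(self, name))


def _from_dict(cls, data: dict[str, Any]):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: "
                         f"{sorted(unknown)}")
    kwargs = {}
    for key, val in data.items():
        ftype = names[key].type
        if dataclasses.is_dataclass(_SECTION_TYPES.get(key)) and isinstance(val, dict):
            kwargs[key] = _from_dict(_SECTION_TYPES[key], val)
        else:
            kwargs[key] = val
    return cls(**kwargs)


_SECTION_TYPES = {
    "simulate": SimulateConfig,
    "qc": QCConfig,
    "cluster": ClusterConfig,
    "integrate": IntegrateConfig,
    "trajectory": TrajectoryConfig,
    "tf": TFConfig,
    "regulons": RegulonConfig,
}


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    return _from_dict(PipelineConfig, data or {})


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def stage_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the root seed (< 2^31)."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % 1_000_003
    return (root_seed * 1_000_003 + h) % (2 ** 31)
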