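"""Top-level tool configuration bundling all stage parameters.

Loadable from YAML or JSON; unspecified sections fall back to the documented
defaults of each stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cnv import CnvParams
from .panels import Mode
from .prioritize import FilterConfig


@dataclass
class QcParams:
    min_depth: int = 20
    cover_frac_max: float = 0.5
    sample_frac_min: float = 0.95
    coverage_thresholds: tuple[int, ...] = (20, 30)


@dataclass
class ToolConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    cnv: CnvParams = field(default_factory=CnvParams)
    qc: QcParams = field(default_factory=QcParams)
    seed: int = 0


def load_config(path: str | Path | None) -> ToolConfig:
    if path is None:
        return ToolConfig()
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    doc = doc or {}
    filters = doc.get("filters", {})
    if "maf_max" in filters:
        filters = dict(filters)
        filters["maf_max"] = {
            Mode(k.upper()): float(v) for k, v in filters["maf_max"].items()
        }
    if "het_vaf_range" in filters:
        filters["het_vaf_range"] = tuple(filters["het_vaf_range"])
    cfg = ToolConfig(
        filters=FilterConfig(**filters),
        cnv=CnvParams(**doc.get("cnv", {})),
        qc=QcParams(**doc.get("qc", {})),
        seed=int(doc.get("seed", 0)),
    )
    return cfg
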