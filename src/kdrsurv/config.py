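"""Pipeline configuration: codon specs, haplotype panel, thresholds.

Configuration is plain YAML; every field has a default matching the standard
four-codon Taiwanese kdr survey, so an empty config is valid.  Each run
writes its resolved configuration next to its outputs for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, TextIO

import yaml

from .genotypes import DEFAULT_CODON_SPECS, CodonSpec
from .phasing import DEFAULT_PANEL_MEMBERS, HaplotypePanel

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class PipelineConfig:
    codon_specs: tuple[CodonSpec, ...] = DEFAULT_CODON_SPECS
    panel: HaplotypePanel = field(default_factory=HaplotypePanel)
    expected_count_cutoff: float = 5.0
    alpha: float = 0.05
    strong_alpha: float = 0.01
    p_decimals: int = 4
    freq_decimals: int = 2
    percent_decimals: int = 1
    reverse_complement: bool = False
    seed: int = 0

    def resolved(self) -> dict[str, Any]:
        """Plain-dict form suitable for YAML provenance output."""
        d = asdict(self)
        d["codon_specs"] = [asdict(s) for s in self.codon_specs]
        d["panel"] = {"name": self.panel.name,
                      "members": sorted(self.panel.members)}
        return d


def load_config(source: str | Path | TextIO | None = None) -> PipelineConfig:
    """Load a pipeline config from YAML; every key is optional."""
    if source is None:
        return PipelineConfig()
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = yaml.safe_load(source) or {}
    cfg = PipelineConfig()
    if "codon_specs" in raw:
        cfg.codon_specs = tuple(CodonSpec(**s) for s in raw["codon_specs"])
    if "panel" in raw:
        panel = raw["panel"]
        if isinstance(panel, dict):
            cfg.panel = HaplotypePanel(frozenset(panel["members"]),
                                       name=panel.get("name", "custom"))
        else:
            cfg.panel = HaplotypePanel(frozenset(panel), name="custom")
    for key in ("expected_count_cutoff", "alpha", "strong_alpha", "p_decimals",
                "freq_decimals", "percent_decimals", "reverse_complement",
                "seed"):
        if key in raw:
            setattr(cfg, key, raw[key])
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.resolved(), fh, sort_keys=False)
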