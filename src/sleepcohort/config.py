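"""Pipeline configuration: every threshold explicit, unknown keys rejected."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .cohort import ValidityThresholds
from .simulate import CohortSpec, DeviceModel


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults reproduce the standard screens.

    ``simulate`` carries the synthetic-cohort parameters; ``thresholds``
    the validity screens; the rest controls the statistical stages and
    output layout.
    """

    out_dir: str = "results/pipeline"
    seed: int = 0
    simulate: dict = field(default_factory=dict)       # CohortSpec overrides
    thresholds: dict = field(default_factory=dict)     # ValidityThresholds overrides
    min_valid_nights: int = 3
    required_sources: Optional[list] = None            # None -> all devices + diary
    agreement_n_iter: int = 5000
    behavior_scales: list = field(default_factory=lambda: [
        "srs_total", "rbsr_total", "cbcl_adhd", "cbcl_anxiety",
        "cbcl_depression", "cshq_total", "vineland_composite",
        "sensory_sensitivity"])
    sleep_outcomes: list = field(default_factory=lambda: ["tst_min", "waso_min"])
    write_hypnograms: bool = False
    make_figures: bool = True
    log_level: str = "INFO"

    def cohort_spec(self) -> CohortSpec:
        kw = dict(self.simulate)
        if "device_models" in kw:
            kw["device_models"] = tuple(
                DeviceModel(**d) for d in kw["device_models"])
        allowed = {f.name for f in dataclasses.fields(CohortSpec)}
        unknown = set(kw) - allowed
        if unknown:
            raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
        kw.setdefault("seed", self.seed)
        return CohortSpec(**kw)

    def validity(self) -> ValidityThresholds:
        allowed = {f.name for f in dataclasses.fields(ValidityThresholds)}
        unknown = set(self.thresholds) - allowed
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return ValidityThresholds(**self.thresholds)


def load_config(path: Path | str | None = None, **overrides: Any
                ) -> PipelineConfig:
    """Load a YAML config; unknown top-level keys raise ValueError."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    allowed = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def config_hash(cfg: PipelineConfig) -> str:
    import hashlib
    import json

    d = dataclasses.asdict(cfg)
    d.pop("out_dir", None)   # where artifacts land does not alter the analysis
    d.pop("log_level", None)
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
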