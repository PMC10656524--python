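"""Declarative run configuration.

A flat, human-diffable YAML file with sections; every threshold defaults
to the study's printed value, unknown keys are rejected (typos in
threshold names must not silently fall back to defaults), and the
effective configuration is echoed into the output directory so a run is
reproducible from its artifacts alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .filters import DnvFilterConfig, RecessiveFilterConfig, TransmittedFilterConfig


@dataclass
class ThresholdBlock:
    frameshift_factor: float = 1.25
    dmis_fraction_default: float = 0.30
    pli_boundaries: tuple = (6.4e-8, 1.9e-3, 0.48)
    pli_constrained_cutoff: float = 0.9
    alpha: float = 0.05
    per_gene_test_families: int = 3
    duplicate_sharing_threshold: float = 0.80
    ibd_band: tuple = (0.45, 0.55)


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "runs/out"
    inputs: dict = field(default_factory=dict)     # named file paths
    thresholds: ThresholdBlock = field(default_factory=ThresholdBlock)
    dnv_filter: DnvFilterConfig = field(default_factory=DnvFilterConfig)
    transmitted_filter: TransmittedFilterConfig = field(default_factory=TransmittedFilterConfig)
    recessive_filter: RecessiveFilterConfig = field(default_factory=RecessiveFilterConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        kwargs: dict = {}
        for name, sub_cls in (
            ("thresholds", ThresholdBlock),
            ("dnv_filter", DnvFilterConfig),
            ("transmitted_filter", TransmittedFilterConfig),
            ("recessive_filter", RecessiveFilterConfig),
        ):
            if name in raw:
                sub_raw = dict(raw[name])
                sub_known = {f.name for f in fields(sub_cls)}
                sub_unknown = set(sub_raw) - sub_known
                if sub_unknown:
                    raise ValueError(f"unknown {name} key(s): {sorted(sub_unknown)}")
                for k, v in sub_raw.items():
                    if isinstance(v, list):
                        sub_raw[k] = tuple(v)
                kwargs[name] = sub_cls(**sub_raw)
        for name in ("seed", "out_dir", "inputs"):
            if name in raw:
                kwargs[name] = raw[name]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True, default_flow_style=False)

    def echo_into(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        target = out / "effective_config.yaml"
        self.to_yaml(target)
        return target
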