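"""Run configuration shared by the CLI entry points."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import yaml

from .calling import CI_METHODS, Thresholds
from .partition import DropletSpec

__all__ = ["RunConfig"]

CALL_HANDLING = ("exclude_inconclusive", "as_negative")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs besides its input tables."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    droplet_spec: DropletSpec = field(default_factory=DropletSpec)
    alpha: float = 0.05
    cnv_ci_method: str = "log_delta"
    call_handling: str = "exclude_inconclusive"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.cnv_ci_method not in CI_METHODS:
            raise ValueError(f"cnv_ci_method must be one of {CI_METHODS}")
        if self.call_handling not in CALL_HANDLING:
            raise ValueError(f"call_handling must be one of {CALL_HANDLING}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Build a config from a flat YAML mapping.

        Threshold fields may appear either at the top level or nested under
        a ``thresholds:`` key; likewise ``droplet_volume_nl``.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        thr_raw = dict(raw.pop("thresholds", {}))
        thr_fields = Thresholds.__dataclass_fields__.keys()
        for k in list(raw):
            if k in thr_fields:
                thr_raw[k] = raw.pop(k)
        spec_raw = dict(raw.pop("droplet_spec", {}))
        for k in list(raw):
            if k in DropletSpec.__dataclass_fields__:
                spec_raw[k] = raw.pop(k)
        known = {k: v for k, v in raw.items() if k in ("alpha", "cnv_ci_method", "call_handling", "seed")}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(thresholds=Thresholds(**thr_raw), droplet_spec=DropletSpec(**spec_raw), **known)

    def with_overrides(self, **kwargs) -> "RunConfig":
        """Copy with non-None keyword overrides (threshold fields included)."""
        thr = {k: v for k, v in kwargs.items()
               if k in Thresholds.__dataclass_fields__ and v is not None}
        spec = {k: v for k, v in kwargs.items()
                if k in DropletSpec.__dataclass_fields__ and v is not None}
        top = {k: v for k, v in kwargs.items()
               if k in ("alpha", "cnv_ci_method", "call_handling", "seed") and v is not None}
        cfg = self
        if thr:
            cfg = replace(cfg, thresholds=replace(cfg.thresholds, **thr))
        if spec:
            cfg = replace(cfg, droplet_spec=replace(cfg.droplet_spec, **spec))
        if top:
            cfg = replace(cfg, **top)
        return cfg

    def to_flat_dict(self) -> dict:
        """Flat key→value view used for provenance headers."""
        out = {
            "alpha": self.alpha,
            "cnv_ci_method": self.cnv_ci_method,
            "call_handling": self.call_handling,
            "seed": self.seed,
            "droplet_volume_nl": self.droplet_spec.droplet_volume_nl,
        }
        for k in Thresholds.__dataclass_fields__:
            out[k] = getattr(self.thresholds, k)
        return out
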