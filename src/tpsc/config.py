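"""Run configuration: defaults, YAML files, and precedence rules."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import yaml

from .exceptions import ValidationError
from .potential import sigma_from_threshold

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "load_yaml_config"]

_DEFAULTS = {
    "r": 0.3,
    "d_min": 5,
    "sigma": None,
    "correlation_mode": "absolute",
    "seed": 1,
    "expr": None,
    "node_weights": None,
    "weights_matrix": None,
    "survival": None,
    "out": "modules.tsv",
    "zero_frac": 0.5,
    "mean_pct": 0.20,
    "var_pct": 0.10,
}


@dataclass
class RunConfig:
    r: float
    d_min: int
    sigma: float
    correlation_mode: str
    seed: int
    expr: str
    node_weights: str
    weights_matrix: str
    survival: str
    out: str
    zero_frac: float
    mean_pct: float
    var_pct: float

    @property
    def variant(self) -> str:
        # TPSC-w iff prior-knowledge node masses are supplied
        return "tpscw" if self.node_weights else "tpsc1"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variant"] = self.variant
        return d


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return raw


def validate_config(flags: dict = None, file_values: dict = None) -> RunConfig:
    """Merge defaults < YAML file < command-line flags and validate.

    Flags set to None are treated as "not given".  sigma, when not
    user-supplied, is derived as sqrt(2)/(3 r); a user-supplied sigma
    that disagrees with the derived value triggers a consistency
    warning (module detection and cluster-count determination then use
    inconsistent scales).
    """
    merged = dict(_DEFAULTS)
    for source in (file_values or {}, flags or {}):
        merged.update({k: v for k, v in source.items() if v is not None})

    if not 0 < merged["r"] < 1:
        raise ValidationError(f"r must be in (0, 1), got {merged['r']}")
    if merged["d_min"] < 0:
        raise ValidationError(f"d_min must be >= 0, got {merged['d_min']}")
    derived = sigma_from_threshold(merged["r"])
    if merged["sigma"] is None:
        merged["sigma"] = derived
    else:
        if merged["sigma"] <= 0:
            raise ValidationError("sigma must be > 0")
        if abs(merged["sigma"] - derived) > 1e-6:
            logger.warning(
                "sigma=%.4f != sqrt(2)/(3r)=%.4f: the weight cutoff and the "
                "field influence range are inconsistent",
                merged["sigma"], derived,
            )
    if merged["correlation_mode"] not in ("absolute", "positive-only"):
        raise ValidationError(
            f"unknown correlation_mode {merged['correlation_mode']!r}"
        )
    merged["d_min"] = int(merged["d_min"])
    merged["seed"] = int(merged["seed"])
    return RunConfig(**merged)
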