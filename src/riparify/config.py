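"""Run configuration: attribute mappings, weights, bins, analysis knobs.

Loaded from YAML; unknown keys are rejected so typos fail loudly. The
value-normalization table accepts both the canonical three-level
ecomorphology vocabulary and the five-level field scheme
(High/Good -> natural, Moderate -> semi_natural, Poor/Bad -> artificial).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .network import Weights
from .riparian import BufferSpec
from .scoring import BinMap, DEFAULT_MAX_DIST_M

DEFAULT_ATTRIBUTE_MAP = {
    "barrier": "barrier", "ec": "ec", "nps": "nps",
    "hdas": "hdas", "restored": "restored", "state": "state",
}

#: raw attribute value -> canonical level; lookups are case-insensitive
DEFAULT_VALUE_MAP = {
    "barrier": {"yes": "yes", "true": "yes", "1": "yes",
                "no": "no", "false": "no", "0": "no",
                "unknown": "unknown", "": "unknown"},
    "ec": {"natural": "natural", "semi_natural": "semi_natural",
           "semi-natural": "semi_natural", "artificial": "artificial",
           # five-level field classification collapsed to three levels
           "high": "natural", "good": "natural",
           "moderate": "semi_natural",
           "poor": "artificial", "bad": "artificial",
           "unknown": "unknown", "": "unknown"},
    "presence": {"present": "present", "yes": "present", "1": "present",
                 "true": "present", "absent": "absent", "no": "absent",
                 "0": "absent", "false": "absent",
                 "unknown": "unknown", "": "unknown"},
}


@dataclass
class Config:
    attribute_map: dict = field(
        default_factory=lambda: dict(DEFAULT_ATTRIBUTE_MAP))
    weights: Weights = field(default_factory=Weights)
    bins: BinMap = field(default_factory=BinMap)
    adjacency_mode: str = "network"      # or "euclidean"
    adjacency_max_dist_m: float = DEFAULT_MAX_DIST_M
    buffer: BufferSpec = field(default_factory=BufferSpec)
    snap_tol_m: float = 1.0
    mmu_m2: float = 50.0
    contiguity: str = "queen"            # or "rook"
    ed_exclude_boundary: bool = False
    report_ndigits: int = 1
    assume_planar: bool = False          # accept lon/lat-looking coords

    def __post_init__(self) -> None:
        if self.adjacency_mode not in ("network", "euclidean"):
            raise ValueError("adjacency_mode must be 'network' or 'euclidean'")
        if self.adjacency_max_dist_m < 0:
            raise ValueError("adjacency_max_dist_m must be >= 0")
        if self.contiguity not in ("queen", "rook"):
            raise ValueError("contiguity must be 'queen' or 'rook'")
        if self.snap_tol_m < 0:
            raise ValueError("snap_tol_m must be >= 0")
        missing = set(DEFAULT_ATTRIBUTE_MAP) - set(self.attribute_map)
        if missing:
            raise ValueError(f"attribute_map missing keys: {sorted(missing)}")

    def digest(self) -> str:
        """Stable hash of the full configuration, for provenance logs."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "Config":
        known = {"attribute_map", "weights", "bins", "adjacency", "buffer",
                 "snap_tol_m", "mmu_m2", "contiguity",
                 "ed_exclude_boundary", "report_ndigits", "assume_planar"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw: dict = {}
        if "attribute_map" in raw:
            kw["attribute_map"] = {**DEFAULT_ATTRIBUTE_MAP,
                                   **raw["attribute_map"]}
        if "weights" in raw:
            w = raw["weights"]
            kw["weights"] = Weights(
                w_barrier=w.get("barrier", 0.25), w_ec=w.get("ec", 0.25),
                w_nps=w.get("nps", 0.25), w_hdas=w.get("hdas", 0.25))
        if "bins" in raw:
            b = raw["bins"]
            kw["bins"] = BinMap(edges=tuple(b["edges"]),
                                labels=tuple(b.get("labels",
                                                   BinMap().labels)))
        if "adjacency" in raw:
            a = dict(raw["adjacency"])
            bad = set(a) - {"mode", "max_dist_m"}
            if bad:
                raise ValueError(f"unknown adjacency keys: {sorted(bad)}")
            kw["adjacency_mode"] = a.get("mode", "network")
            kw["adjacency_max_dist_m"] = a.get("max_dist_m",
                                               DEFAULT_MAX_DIST_M)
        if "buffer" in raw:
            b = raw["buffer"]
            kw["buffer"] = BufferSpec(
                main_width_m=b.get("main_width_m", 60.0),
                side_width_m=b.get("side_width_m", 40.0),
                cap_style=b.get("cap_style", "round"))
        for key in ("snap_tol_m", "mmu_m2", "contiguity",
                    "ed_exclude_boundary", "report_ndigits",
                    "assume_planar"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)
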