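"""Run configuration: station presets and YAML round-trip.

The ILT levels L1/L2, dir_percent, n_dir and the per-station
pm_thresholds have no published values; the defaults below follow the
package's own conventions (L1/L2 straddling the adipose/lean boundary,
half of 32 directions pooled) with the thresholds calibrated once on
seeded phantom training ensembles (see :mod:`bodycomp.calibrate`).  The
ray caps equal the largest in-support chord the phantom geometries can
produce, where they are exactly equivalent to unlimited rays.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .core import HUBands
from .ilt import ILTParams
from .liver import LiverConfig

__all__ = [
    "ABDOMEN_ILT",
    "LIVER_CAVITY_ILT",
    "THIGH_SAT_ILT",
    "THIGH_DEEP_ILT",
    "THIGH_DEPTH_MM",
    "BACK_THRESHOLD",
    "RunConfig",
    "default_config",
]

# Phantom-calibrated per-station ILT presets (plateau midpoints of the
# calibration sweeps in bodycomp.calibrate).
ABDOMEN_ILT = ILTParams(pm_threshold=0.10, max_range_mm=380.0)
LIVER_CAVITY_ILT = ILTParams(pm_threshold=0.10, max_range_mm=380.0)
THIGH_SAT_ILT = ILTParams(pm_threshold=0.04, max_range_mm=180.0)
THIGH_DEEP_ILT = ILTParams(pm_threshold=0.20, max_range_mm=180.0)
THIGH_DEPTH_MM = 10.5  # morphological erosion depth, calibrated on phantoms
BACK_THRESHOLD = 0.5


@dataclass
class RunConfig:
    """Everything a reproducible station run needs."""

    bands: HUBands = field(default_factory=HUBands)
    abdomen_ilt: ILTParams = field(default_factory=lambda: ABDOMEN_ILT)
    liver_cavity_ilt: ILTParams = field(default_factory=lambda: LIVER_CAVITY_ILT)
    thigh_sat_ilt: ILTParams = field(default_factory=lambda: THIGH_SAT_ILT)
    thigh_deep_ilt: ILTParams = field(default_factory=lambda: THIGH_DEEP_ILT)
    liver: LiverConfig = field(default_factory=lambda: LiverConfig(ilt=LIVER_CAVITY_ILT))
    back_threshold: float = BACK_THRESHOLD
    thigh_method: str = "ilt"
    depth_mm: float = THIGH_DEPTH_MM
    output_dir: str = "."
    seed: int = 0

    def __post_init__(self):
        if self.thigh_method not in ("ilt", "morph", "both"):
            raise ValueError("thigh_method must be 'ilt', 'morph' or 'both'")
        if not 0.0 <= self.back_threshold <= 1.0:
            raise ValueError("back_threshold must be in [0, 1]")
        if self.depth_mm <= 0:
            raise ValueError("depth_mm must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        # tuples -> lists for YAML friendliness
        return yaml.safe_load(yaml.safe_dump(d))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)

        def _tup(x):
            return tuple(x) if isinstance(x, list) else x

        if "bands" in d:
            b = {k: _tup(v) for k, v in d["bands"].items()}
            d["bands"] = HUBands(**b)
        for key in ("abdomen_ilt", "liver_cavity_ilt", "thigh_sat_ilt", "thigh_deep_ilt"):
            if key in d and isinstance(d[key], dict):
                d[key] = ILTParams(**d[key])
        if "liver" in d and isinstance(d["liver"], dict):
            lv = dict(d["liver"])
            if isinstance(lv.get("ilt"), dict):
                lv["ilt"] = ILTParams(**lv["ilt"])
            if "range_percentiles" in lv:
                lv["range_percentiles"] = _tup(lv["range_percentiles"])
            d["liver"] = LiverConfig(**lv)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config() -> RunConfig:
    return RunConfig()
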