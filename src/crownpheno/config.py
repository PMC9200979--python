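"""Run configuration: every tunable the pipeline uses, serializable so a
run is reproducible from (inputs, config)."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields


@dataclass
class RunConfig:
    """Pipeline settings with the package defaults.

    Reference dims are the calibration cuboid (cm); ``octree_depth`` sets
    the volumetric-remesh resolution (bounding-box diagonal / 2**depth).
    """

    reference_known_dims_cm: tuple = (12.5, 12.5, 34.0)
    reference_dim_selector: str = "longest"
    repair_octree_depth: int = 8
    repair_closing_radius: int = 3
    noise_min_fraction: float = 0.01
    stem_cut_height_cm: float = 0.0
    hub_radius_cm: float = 4.0
    k_lowest_angles: int = 3
    min_root_volume_cm3: float = 5.0
    support_normal: tuple = (0.0, -1.0, 0.0)
    seed: int = 0

    @property
    def known_dim_cm(self) -> float:
        sel = {"shortest": 0, "middle": 1, "longest": 2}
        return sorted(self.reference_known_dims_cm)[
            sel[self.reference_dim_selector]]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Parse a simple ``key = value`` text config."""
        kwargs = {}
        valid = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key not in valid:
                    raise KeyError(f"unknown config key {key!r}")
                current = getattr(cls(), key)
                if isinstance(current, tuple):
                    kwargs[key] = tuple(float(x) for x in val.split(","))
                elif isinstance(current, bool):
                    kwargs[key] = val.lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    kwargs[key] = int(val)
                elif isinstance(current, float):
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = val
        return cls(**kwargs)
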