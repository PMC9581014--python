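"""Run configuration shared by the CLI commands.

All tunables of the pipeline in one place, with the defaults used
throughout: 30-residue loops, 7-residue seed segments, a 5.0 A VdW
contact radius and a 3.5 A H-bond radius, unit pseudocount and uniform
background for the sequence profile, and unit per-feature scale factors.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    loop_length: int = 30
    seed_segment_length: int = 7
    vdw_radius: float = 5.0       # A
    hbond_radius: float = 3.5     # A
    pseudocount: float = 1.0
    scan_threshold: float = 10.0  # bits
    max_iterations: int = 20
    tolerance: float = 1e-9
    max_K: int = 3                # dihedral mixture components tried
    scale_d: float = 1.0          # per-feature scalar factors
    scale_v: float = 1.0
    scale_hA: float = 1.0
    scale_hD: float = 1.0
    invert_spread_weights: bool = False
    switch_margin: float = 0.0
    sequence_mode: str = "expected"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0 or self.hbond_radius <= 0:
            raise ValueError("radii must be positive")
        if self.loop_length < 1 or self.seed_segment_length < 1:
            raise ValueError("lengths must be >= 1")
        if self.seed_segment_length > self.loop_length:
            raise ValueError("seed segment cannot exceed the loop length")

    @property
    def scale_factors(self) -> dict[str, float]:
        return {"d": self.scale_d, "v": self.scale_v,
                "hA": self.scale_hA, "hD": self.scale_hD}

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Flat key = value text config; '#' starts a comment."""
        values: dict[str, object] = {}
        fields = {f.name: f.type for f in
                  cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, raw = (part.strip() for part in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                default = getattr(cls(), key)
                if isinstance(default, bool):
                    values[key] = raw.lower() in ("1", "true", "yes", "on")
                elif isinstance(default, int):
                    values[key] = int(raw)
                elif isinstance(default, float):
                    values[key] = float(raw)
                else:
                    values[key] = raw.strip("\"'")
        return cls(**values)  # type: ignore[arg-type]
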