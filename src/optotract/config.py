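"""Run configuration shared across the pipeline stages."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import yaml


@dataclasses.dataclass
class RunConfig:
    """Parameters governing streamline selection, map correlation and spike tests.

    Attributes
    ----------
    seed_sphere_diameter_mm
        Diameter of the spherical region of interest centred on each
        subcortical injection site used to select streamlines (1 mm default).
    depth_tolerance_mm, angle_tolerance_deg
        Half-widths of the acceptance window around a candidate cortical
        depth Δ and angle-to-normal θ when filtering streamline terminals.
        Defaults are half the spacing of the default parameter grid.
    correlation_radius_mm
        Geodesic radius of the surface neighborhood over which local Pearson
        correlation between tractography and histology maps is computed.
    correlation_threshold
        Local r above which a vertex counts toward "correlated surface area"
        (strict inequality; 0.5 default).
    gof_alpha
        Family-wise significance level for the point-process goodness-of-fit
        suite; each of the four tests runs at ``gof_alpha / 4`` (Bonferroni).
    rng_seed
        Seed for every stochastic component of a run.
    grid_depths_mm, grid_angles_deg
        The (Δ, θ) grid searched during parameter optimization.
    """

    seed_sphere_diameter_mm: float = 1.0
    depth_tolerance_mm: float = 0.5
    angle_tolerance_deg: float = 7.5
    correlation_radius_mm: float = 3.0
    correlation_threshold: float = 0.5
    gof_alpha: float = 0.05
    rng_seed: int = 0
    grid_depths_mm: Sequence[float] = (2.0, 3.0)
    grid_angles_deg: Sequence[float] = (0.0, 30.0, 45.0)
    density_smoothing_mm: float = 2.0

    def __post_init__(self) -> None:
        for name in ("seed_sphere_diameter_mm", "correlation_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.depth_tolerance_mm < 0 or self.angle_tolerance_deg < 0:
            raise ValueError("tolerances must be >= 0")
        if not -1 < self.correlation_threshold < 1:
            raise ValueError("correlation_threshold must lie in (-1, 1)")
        if not 0 < self.gof_alpha < 1:
            raise ValueError("gof_alpha must lie in (0, 1)")
        if self.density_smoothing_mm < 0:
            raise ValueError("density_smoothing_mm must be >= 0")
        for name in ("grid_depths_mm", "grid_angles_deg"):
            vals = list(getattr(self, name))
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing")
            setattr(self, name, tuple(float(v) for v in vals))

    @property
    def seed_sphere_radius_mm(self) -> float:
        return self.seed_sphere_diameter_mm / 2.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
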