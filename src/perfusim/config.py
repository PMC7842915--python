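"""Run configuration: a flat, YAML-serializable schema with full defaults.

Two runs with equal effective configs produce identical outputs; the
resolved config is written alongside every run's artifacts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    # network source: either a file...
    network_path: str | None = None
    network_dialect: str = "csv"
    # ...or generator parameters
    extent_um: tuple = (300.0, 300.0, 300.0)
    target_density_per_mm3: float = 11600.0
    n_penetrating_pairs: int = 1
    seed: int = 1
    # depth separating pial from penetrating vessels when classifying a
    # network read from file (generated networks carry their classes)
    surface_depth_um: float = 10.0

    # grid
    grid_cells: tuple = (64, 64, 64)

    # physiology (defaults follow the standard murine-cortex parameter set)
    diffusivity_um2_s: float = 1800.0
    permeability_um2_s: float = 2400.0
    endothelial_thickness_um: float = 1.0
    metabolic_rate_per_ms: float = 14.17
    pressure_drop_mmhg: float = 115.0
    inlet_oxygen_mmhg: float = 68.5
    inlet_hematocrit: float = 0.35
    viscosity_model: str = "in_vitro"
    skimming_model: str = "proportional"
    beta_model: str = "rbc"

    # solver
    flow_tol: float = 1e-6
    flow_max_iter: int = 100
    oxygen_rtol: float = 1e-10
    preconditioner: str = "ilu"
    restart: int = 200
    hierarchy_levels: int = 1

    # scenario
    scenario: str = "young"
    occlusion_fraction: float = 0.30
    hematocrit_factor: float = 0.70

    # analysis
    hypoxia_thresholds_mmhg: tuple = (5.0, 10.0, 15.0)
    depth_planes_um: tuple = (120.0, 280.0, 480.0, 680.0, 880.0)
    roi_box_um: tuple | None = None

    # output
    output_dir: str = "perfusim_run"
    field_format: str = "vtk_image"

    def validate(self) -> None:
        if self.network_path is None and any(e <= 0 for e in self.extent_um):
            raise ParameterError("extent_um must be positive")
        if any(c < 2 for c in self.grid_cells):
            raise ParameterError("grid_cells must be at least 2 per axis")
        if self.scenario not in ("young", "occl", "hct", "combined"):
            raise ParameterError(f"unknown scenario {self.scenario!r}")
        if self.hierarchy_levels < 1:
            raise ParameterError("hierarchy_levels must be >= 1")

    def to_yaml(self, path=None) -> str:
        doc = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in asdict(self).items()}
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            doc = yaml.safe_load(Path(source).read_text())
        else:
            doc = yaml.safe_load(source)
        if not isinstance(doc, dict):
            raise ParameterError("config document must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in doc.items():
            if isinstance(cls.__dataclass_fields__[k].default, tuple) and v is not None:
                v = tuple(v)
            elif isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    SCENARIO_MODES = {"young": "young", "occl": "occlusions",
                      "hct": "hematocrit", "combined": "combined"}
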