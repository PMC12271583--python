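"""Run configuration shared by the pipeline and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .exceptions import InvalidParameterError

__all__ = ["RunConfig", "OUTPUT_SUFFIXES"]

# dataset naming convention: suffix appended to the PDB id per output kind
OUTPUT_SUFFIXES = {
    "experimental": "",
    "simulated": "_situs_simulated",
    "regression": "_regression_situs",
    "classification": "_classification_situs",
    "atom_type": "_classification_types_situs",
}


@dataclass
class RunConfig:
    """Parameters of one label-generation run.

    ``voxel_target`` is the standardized voxel size (1 Å in the published
    dataset); ``neighbor_radius`` the labeling neighborhood (6 Å);
    ``kernel_resolution`` the simulated-map nominal resolution, ideally the
    entry's reported resolution, 2 Å otherwise.
    """

    voxel_target: float = 1.0
    neighbor_radius: float = 6.0
    kernel_resolution: float = 2.0
    kernel_cutoff: float = 4.0
    amplitude_mode: str = "uniform"
    origin_dialect: str = "auto"
    label_mode: int = 2          # MRC write mode for label maps (2=float32, 0=int8)
    seed: int = 0
    pdb_id: str | None = None
    naming: str = "{pdb_id}{suffix}.mrc"
    include_hetero: bool = True

    def __post_init__(self) -> None:
        for name in ("voxel_target", "neighbor_radius", "kernel_resolution"):
            if not (getattr(self, name) > 0):
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if "{pdb_id}" not in self.naming:
            raise InvalidParameterError("naming template must contain '{pdb_id}'")

    def output_name(self, pdb_id: str, kind: str) -> str:
        return self.naming.format(pdb_id=pdb_id, suffix=OUTPUT_SUFFIXES[kind])

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides (CLI flags) take precedence."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
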