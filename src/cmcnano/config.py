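"""Run configuration: serializable defaults echoed beside every CLI output."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Global defaults for a reproducible run."""

    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"
    # physics
    eps_r: float = 80.0
    ionic_strength: float = 0.1
    temperature: float = 298.0
    # generator geometry (nm)
    bond_length: float = 0.515
    charge_bead_offset: float = 0.35
    alkyl_bead_offset: float = 0.55
    grid_spacing: float = 0.2
    # clustering cutoffs (A)
    alkyl_cutoff: float = 6.0
    acid_cutoff: float = 8.0
    contact_distance: float = 3.0
    proximity_low: float = 10.0
    proximity_high: float = 15.0
    # bookkeeping
    mass_convention: str = "sodium_salt"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def write_sidecar(self, output_path) -> Path:
        """Echo the effective config next to an output file."""
        sidecar = Path(str(output_path) + ".config.yaml")
        self.to_yaml(sidecar)
        return sidecar
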