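"""Run manifests: a reproducibility record written next to every output set.

A manifest snapshots the configuration, environment spec, seed(s) and
package version, and inventories the output files with SHA-256 checksums.
Re-running the same command with the same manifest inputs reproduces every
deterministic output bit-exactly (and stochastic outputs exactly, since all
randomness is seeded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .config import EnvironmentSpec, GameConfig, SweepGrid, config_to_json


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass(frozen=True)
class RunManifest:
    command: str
    config: GameConfig
    env: EnvironmentSpec
    seed: int | None
    grid: SweepGrid | None = None
    version: str = ""
    files: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "command": self.command,
            **config_to_json(self.config, self.env),
            "seed": self.seed,
            "version": self.version,
            "files": self.files,
        }
        if self.grid is not None:
            payload["sweep"] = {**dataclasses.asdict(self.grid),
                                "alpha_values": list(self.grid.alpha_values),
                                "beta_values": list(self.grid.beta_values)}
        return json.dumps(payload, indent=2, sort_keys=True)


def write_manifest(directory, command: str, config: GameConfig,
                   env: EnvironmentSpec, seed: int | None,
                   outputs, grid: SweepGrid | None = None) -> Path:
    """Checksum ``outputs`` (paths) and write ``manifest.json`` in
    ``directory``; returns the manifest path."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {Path(p).name: _sha256(Path(p)) for p in outputs}
    manifest = RunManifest(command=command, config=config, env=env,
                           seed=seed, grid=grid, version=__version__,
                           files=files)
    path = directory / "manifest.json"
    path.write_text(manifest.to_json())
    return path
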