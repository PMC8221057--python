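"""Configuration file I/O: XYZ coordinates plus a JSON sidecar.

A configuration is stored as an XYZ file with one pseudo-atom ("X") per
molecular center and a companion JSON sidecar carrying orientations (as
quaternions), the monomer mode set, diagonal disorder and metadata.
Round trips are lossless to double precision: coordinates are written
with 17 significant digits and JSON floats use Python's repr.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .structures import MolecularConfiguration, MonomerModeSet

__all__ = ["write_xyz", "read_xyz", "load_config_file"]


def write_xyz(config: MolecularConfiguration, xyz_path,
              sidecar_path=None) -> Tuple[Path, Path]:
    """Write a configuration as XYZ + JSON sidecar; returns both paths."""
    xyz_path = Path(xyz_path)
    sidecar_path = Path(sidecar_path) if sidecar_path is not None \
        else xyz_path.with_suffix(".json")
    n = config.n_molecules
    with open(xyz_path, "w", encoding="utf-8") as fh:
        fh.write(f"{n}\n")
        fh.write("molecular centers; orientations and modes in sidecar\n")
        for p in config.positions:
            fh.write(f"X {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    quats = Rotation.from_matrix(config.orientations).as_quat().reshape(n, 4)
    sidecar = {
        "orientations_quat_xyzw": quats.tolist(),
        "mode_set": config.mode_set.to_dict(),
        "freq_offsets": None if config.freq_offsets is None
        else config.freq_offsets.tolist(),
        "metadata": config.metadata,
    }
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, sort_keys=True, indent=1)
    return xyz_path, sidecar_path


def read_xyz(xyz_path, sidecar_path=None) -> MolecularConfiguration:
    """Read a configuration written by :func:`write_xyz`."""
    xyz_path = Path(xyz_path)
    sidecar_path = Path(sidecar_path) if sidecar_path is not None \
        else xyz_path.with_suffix(".json")
    with open(xyz_path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    n = int(lines[0].strip())
    positions = np.array([[float(x) for x in line.split()[1:4]]
                          for line in lines[2:2 + n]])
    with open(sidecar_path, encoding="utf-8") as fh:
        sidecar = json.load(fh)
    quats = np.asarray(sidecar["orientations_quat_xyzw"], dtype=float)
    orients = Rotation.from_quat(quats).as_matrix().reshape(n, 3, 3)
    offsets = sidecar.get("freq_offsets")
    return MolecularConfiguration(
        positions=positions,
        orientations=orients,
        mode_set=MonomerModeSet.from_dict(sidecar["mode_set"]),
        freq_offsets=None if offsets is None else np.asarray(offsets),
        metadata=sidecar.get("metadata", {}),
    )


def load_config_file(path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
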