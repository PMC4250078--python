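"""File formats: structure import, the internal trajectory container, result tables.

No standard MD trajectory format carries pairwise forces or the labelling
the analysis needs, so the canonical on-disk trajectory is an HDF5 container
with explicit unit metadata; PDB/GRO structure files are import adapters
(parsed through MDAnalysis) that yield a topology skeleton to be completed
with masses, radii and role/side labels from configuration rules.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import h5py
import numpy as np

from .errors import InvalidParameterError, StructureParseError, UnitMismatchError
from .system import Frame, Topology, Trajectory

_UNITS = {"length": "nm", "time": "ps", "mass": "u", "velocity": "nm/ps"}


# ------------------------------------------------------------------ structures


def _first_bad_line(path: Path) -> int | None:
    """Best-effort scan for the first malformed line of a PDB/GRO file."""
    lines = path.read_text().splitlines()
    suffix = path.suffix.lower()
    if suffix == ".gro":
        if len(lines) < 2:
            return len(lines)
        try:
            n = int(lines[1].strip())
        except ValueError:
            return 2
        if len(lines) < n + 3:
            return len(lines)
        for i, line in enumerate(lines[2 : 2 + n], start=3):
            if len(line) < 44:
                return i
        return None
    known = ("ATOM", "HETATM", "TER", "END", "REMARK", "TITLE", "CRYST1", "MODEL", "ENDMDL", "CONECT", "HEADER")
    for i, line in enumerate(lines, start=1):
        if line.strip() and not line.startswith(known):
            return i
        if line.startswith(("ATOM", "HETATM")) and len(line) < 54:
            return i
    return None


def read_structure(
    path: str | Path,
    role_rules: dict[str, list[str]] | None = None,
    side_rules: dict[str, list[str]] | None = None,
    default_mass: float = 12.0,
    default_radius: float = 0.15,
) -> Topology:
    """Topology skeleton from a PDB or GRO file.

    Atom names, residue ids and chain/segment assignments come from the file;
    masses and radii from per-element lookups (overridable); roles and sides
    from ``{tag: [atom names]}`` rules, defaulting to ``solvent`` / ``none``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:
            raise StructureParseError(f"cannot parse {path.name}: {exc}", line=_first_bad_line(path)) from exc
    atoms = u.atoms
    names = atoms.names
    mass_table = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06}
    elements = np.array([next((e for e in ("P", "S", "H", "C", "N", "O") if n.upper().startswith(e)), "C") for n in names])
    masses = np.array([mass_table.get(e, default_mass) for e in elements])
    roles = np.full(len(atoms), "solvent", dtype=object)
    sides = np.full(len(atoms), "none", dtype=object)
    for tag, rule_names in (role_rules or {}).items():
        roles[np.isin(names, rule_names)] = tag
    for tag, rule_names in (side_rules or {}).items():
        sides[np.isin(names, rule_names)] = tag
    try:
        chains = np.array([ord(s[0].upper()) - ord("A") if s and s[0].isalpha() else -1 for s in atoms.segids])
    except (AttributeError, mda.exceptions.NoDataError):
        chains = np.full(len(atoms), -1)
    return Topology(
        masses=masses,
        radii=np.full(len(atoms), default_radius),
        elements=elements,
        resids=np.asarray(atoms.resids),
        monomers=chains,
        sides=sides.astype(str),
        roles=roles.astype(str),
    )


# ------------------------------------------------------------------ trajectories


def save_trajectory(trajectory: Trajectory, path: str | Path, seed: int | None = None, config_hash: str | None = None) -> Path:
    """Write the internal HDF5 trajectory container (lossless, with unit metadata)."""
    path = Path(path)
    topo = trajectory.topology
    with h5py.File(path, "w") as h5:
        for key, val in _UNITS.items():
            h5.attrs[f"units_{key}"] = val
        h5.attrs["n_particles"] = topo.n_particles
        h5.attrs["frame_spacing_ps"] = trajectory.frame_spacing
        if seed is not None:
            h5.attrs["seed"] = seed
        if config_hash is not None:
            h5.attrs["config_hash"] = config_hash
        g = h5.create_group("topology")
        g.create_dataset("masses", data=topo.masses)
        g.create_dataset("radii", data=topo.radii)
        str_dt = h5py.string_dtype()
        for name in ("elements", "sides", "roles"):
            g.create_dataset(name, data=[str(x) for x in getattr(topo, name)], dtype=str_dt)
        g.create_dataset("resids", data=np.asarray(topo.resids, dtype=np.int64))
        g.create_dataset("monomers", data=np.asarray(topo.monomers, dtype=np.int64))
        g.create_dataset("bonds", data=topo.bonds)
        g.create_dataset("bond_k", data=topo.bond_k)
        g.create_dataset("bond_r0", data=topo.bond_r0)
        g.create_dataset("angles", data=topo.angles)
        g.create_dataset("angle_k", data=topo.angle_k)
        g.create_dataset("angle_theta0", data=topo.angle_theta0)
        g.create_dataset("lj_epsilon", data=topo.lj_epsilon)
        g.create_dataset("lj_sigma", data=topo.lj_sigma)
        g.create_dataset("exclusions", data=topo.exclusions)
        h5.create_dataset("positions", data=trajectory.positions_array())
        h5.create_dataset("boxes", data=np.stack([f.box for f in trajectory]))
        h5.create_dataset("times", data=trajectory.times)
        if trajectory.has_velocities:
            h5.create_dataset("velocities", data=np.stack([f.velocities for f in trajectory]))
    return path


def load_trajectory(
    path: str | Path,
    start: int = 0,
    stop: int | None = None,
    stride: int = 1,
) -> Trajectory:
    """Read the internal container back; supports frame-range and stride selection.

    Raises :class:`UnitMismatchError` if the file declares different units;
    a file without velocities loads fine, with ``has_velocities`` False (the
    kinetic stress term is then unavailable).
    """
    path = Path(path)
    with h5py.File(path, "r") as h5:
        for key, val in _UNITS.items():
            attr = f"units_{key}"
            if attr not in h5.attrs:
                raise InvalidParameterError(f"corrupt trajectory container: missing {attr}")
            if h5.attrs[attr] != val:
                raise UnitMismatchError(f"{attr}={h5.attrs[attr]!r}, expected {val!r}")
        required = {"positions", "boxes", "times", "topology"}
        if not required <= set(h5.keys()):
            raise InvalidParameterError("corrupt trajectory container: missing datasets")
        g = h5["topology"]
        topo = Topology(
            masses=g["masses"][:],
            radii=g["radii"][:],
            elements=g["elements"].asstr()[:],
            resids=g["resids"][:],
            monomers=g["monomers"][:],
            sides=g["sides"].asstr()[:],
            roles=g["roles"].asstr()[:],
            bonds=g["bonds"][:],
            bond_k=g["bond_k"][:],
            bond_r0=g["bond_r0"][:],
            angles=g["angles"][:],
            angle_k=g["angle_k"][:],
            angle_theta0=g["angle_theta0"][:],
            lj_epsilon=g["lj_epsilon"][:],
            lj_sigma=g["lj_sigma"][:],
            exclusions=g["exclusions"][:],
        )
        sel = slice(start, stop, stride)
        pos = h5["positions"][sel]
        boxes = h5["boxes"][sel]
        times = h5["times"][sel]
        vel = h5["velocities"][sel] if "velocities" in h5 else None
        spacing = float(h5.attrs["frame_spacing_ps"]) * stride
    frames = [
        Frame(
            time=float(times[i]),
            positions=pos[i],
            box=boxes[i],
            velocities=None if vel is None else vel[i],
        )
        for i in range(len(times))
    ]
    return Trajectory(topology=topo, frames=frames, frame_spacing=spacing)
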