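"""Core particle-system containers: Topology, Frame, Trajectory, PairForce.

These are deliberately plain, numpy-backed dataclasses rather than wrappers
around an MD library's universe object: the stress machinery needs pairwise
forces, which no standard trajectory format carries, so the package owns its
containers and treats MDAnalysis structures as an import adapter (see
:mod:`mechanotrace.io`).

Units: nm, ps, u, pN throughout (see :mod:`mechanotrace.units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import InvalidParameterError, MinimumImageError

#: Recognised particle role tags.
ROLES = frozenset(
    {
        "protein",
        "lipid-head-P",
        "lipid-head-N-acceptor-O",
        "lysine-N",
        "lipid-tail-short",
        "lipid-tail-long",
        "solvent",
    }
)

#: Recognised membrane-side tags.
SIDES = frozenset({"cytoplasmic", "periplasmic", "none"})


def minimum_image(vectors: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap separation vector(s) into the minimum-image convention for an orthorhombic box."""
    box = np.asarray(box, dtype=float)
    return vectors - box * np.round(vectors / box)


@dataclass
class Topology:
    """Static description of a particle system.

    Per-particle arrays (length n): ``masses`` (u), ``radii`` (nm), ``elements``
    (chemical label), ``resids`` (molecule/residue id), ``monomers`` (protein
    monomer id 0-4, -1 for none), ``sides`` (membrane side tag), ``roles``
    (functional role tag). Interaction terms: harmonic bonds, optional harmonic
    angles, per-particle Lennard-Jones parameters with a pair exclusion list.
    """

    masses: np.ndarray
    radii: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    monomers: np.ndarray
    sides: np.ndarray
    roles: np.ndarray
    bonds: np.ndarray = field(default=None)  # (nb, 2) int
    bond_k: np.ndarray = field(default=None)  # pN/nm
    bond_r0: np.ndarray = field(default=None)  # nm
    angles: np.ndarray = field(default=None)  # (na, 3) int, vertex is the middle index
    angle_k: np.ndarray = field(default=None)  # pN*nm/rad^2
    angle_theta0: np.ndarray = field(default=None)  # rad
    lj_epsilon: np.ndarray = field(default=None)  # kJ/mol, 0 = no LJ
    lj_sigma: np.ndarray = field(default=None)  # nm
    exclusions: np.ndarray = field(default=None)  # (ne, 2) int, unordered pairs

    def __post_init__(self):
        n = len(self.masses)
        self.masses = np.asarray(self.masses, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        for name in ("elements", "resids", "monomers", "sides", "roles"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if self.bonds is None:
            self.bonds = np.empty((0, 2), dtype=int)
            self.bond_k = np.empty(0)
            self.bond_r0 = np.empty(0)
        if self.angles is None:
            self.angles = np.empty((0, 3), dtype=int)
            self.angle_k = np.empty(0)
            self.angle_theta0 = np.empty(0)
        if self.lj_epsilon is None:
            self.lj_epsilon = np.zeros(n)
            self.lj_sigma = np.zeros(n)
        if self.exclusions is None:
            self.exclusions = np.empty((0, 2), dtype=int)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        self.angles = np.asarray(self.angles, dtype=int).reshape(-1, 3)
        self.exclusions = np.asarray(self.exclusions, dtype=int).reshape(-1, 2)
        # normalize exclusions to sorted unique pairs -> symmetry by construction
        if len(self.exclusions):
            self.exclusions = np.unique(np.sort(self.exclusions, axis=1), axis=0)
        self.validate()

    def validate(self) -> None:
        n = self.n_particles
        if n == 0:
            raise InvalidParameterError("topology has no particles")
        if np.any(self.masses <= 0):
            raise InvalidParameterError("all particle masses must be > 0")
        if np.any(self.radii < 0):
            raise InvalidParameterError("particle radii must be >= 0")
        for arr, label in ((self.bonds, "bond"), (self.angles, "angle"), (self.exclusions, "exclusion")):
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise InvalidParameterError(f"{label} indices out of range")
        if self.bonds.size and np.any(self.bonds[:, 0] == self.bonds[:, 1]):
            raise InvalidParameterError("bond indices must be distinct")
        bad_sides = set(np.unique(self.sides)) - SIDES
        if bad_sides:
            raise InvalidParameterError(f"unknown side tags: {bad_sides}")
        bad_roles = set(np.unique(self.roles)) - ROLES
        if bad_roles:
            raise InvalidParameterError(f"unknown role tags: {bad_roles}")

    @property
    def n_particles(self) -> int:
        return len(self.masses)

    def select(
        self,
        role: str | Sequence[str] | None = None,
        side: str | None = None,
        element: str | None = None,
        resid: int | None = None,
    ) -> np.ndarray:
        """Index array of particles matching all given criteria."""
        mask = np.ones(self.n_particles, dtype=bool)
        if role is not None:
            roles = [role] if isinstance(role, str) else list(role)
            mask &= np.isin(self.roles, roles)
        if side is not None:
            mask &= self.sides == side
        if element is not None:
            mask &= self.elements == element
        if resid is not None:
            mask &= self.resids == resid
        return np.flatnonzero(mask)

    def is_excluded(self, i: int, j: int) -> bool:
        if not len(self.exclusions):
            return False
        pair = sorted((i, j))
        return bool(np.any((self.exclusions[:, 0] == pair[0]) & (self.exclusions[:, 1] == pair[1])))


@dataclass
class Frame:
    """One trajectory snapshot: time (ps), positions (nm), velocities (nm/ps), box (nm)."""

    time: float
    positions: np.ndarray
    box: np.ndarray
    velocities: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if np.any(self.box <= 0):
            raise InvalidParameterError("box lengths must be > 0")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
            if self.velocities.shape != self.positions.shape:
                raise InvalidParameterError("velocities must match positions shape")

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def separation(self, i: int, j: int) -> np.ndarray:
        """Minimum-image vector from particle i to particle j (x_j - x_i)."""
        d = minimum_image(self.positions[j] - self.positions[i], self.box)
        if np.any(np.abs(d) > self.box / 2 + 1e-12):
            raise MinimumImageError(f"pair ({i}, {j}) separation ambiguous under minimum image")
        return d


@dataclass
class Trajectory:
    """A topology plus an ordered sequence of frames with constant particle count."""

    topology: Topology
    frames: list[Frame]
    frame_spacing: float = 1.0  # ps

    def __post_init__(self):
        if not self.frames:
            raise InvalidParameterError("trajectory must contain at least one frame")
        n = self.topology.n_particles
        times = []
        for f in self.frames:
            if f.n_particles != n:
                raise InvalidParameterError("frame particle count differs from topology")
            times.append(f.time)
        if np.any(np.diff(times) < 0):
            raise InvalidParameterError("frames must be time-ordered")
        self.has_velocities = all(f.velocities is not None for f in self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def positions_array(self) -> np.ndarray:
        """(n_frames, n_particles, 3) stacked positions."""
        return np.stack([f.positions for f in self.frames])


@dataclass
class PairForce:
    """Central force record: ``f`` is the force (pN) on particle ``i`` exerted by ``j``.

    Newton's third law holds by convention: the force on j from i is ``-f``.
    For pair potentials and the central-force decomposition of angle terms,
    ``f`` is parallel to the minimum-image separation r_ij.
    """

    i: int
    j: int
    f: np.ndarray

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float).reshape(3)
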