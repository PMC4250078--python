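"""Balanced radial pulling-force plans for steered lipid-unbinding protocols.

Each tightly-bound lipid is pulled along the in-plane vector from the
protein center of mass to its free-tail center of mass, tilted by a polar
angle theta: 0 deg is a purely lateral pull, 90 deg purely perpendicular,
so the per-lipid force is F (cos(theta) e_radial + sin(theta) n_leaflet).
A counter-balancing force of magnitude n F sin(theta) on the opposite
leaflet's center of mass keeps the net vertical force exactly zero; radial
symmetry keeps the net in-plane force zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, SingularGeometryError
from .system import Frame, Topology


@dataclass
class PullPlan:
    """Per-lipid pulling forces plus the leaflet counterforce.

    ``directions`` are the in-plane unit vectors, ``forces`` the full 3-D
    per-lipid force vectors (pN, each of magnitude F), ``counterforce`` the
    balancing vector applied to the opposite leaflet's center of mass.
    """

    directions: np.ndarray  # (n, 3) in-plane unit vectors
    magnitude: float  # pN
    polar_angle: float  # degrees
    forces: np.ndarray  # (n, 3) pN
    counterforce: np.ndarray  # (3,) pN
    leaflet_normal: np.ndarray  # (3,) outward unit normal of the pulled leaflet

    @property
    def n_lipids(self) -> int:
        return len(self.directions)

    def validate(self) -> None:
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise InvalidParameterError("pull directions must be unit vectors")
        mags = np.linalg.norm(self.forces, axis=1)
        if not np.allclose(mags, self.magnitude, rtol=1e-12, atol=1e-9):
            raise InvalidParameterError("per-lipid force magnitude must equal F")
        vert = self.forces @ self.leaflet_normal
        if abs(vert.sum() + self.counterforce @ self.leaflet_normal) > 1e-9 * max(self.magnitude, 1.0):
            raise InvalidParameterError("vertical force balance violated")


def radial_directions(
    frame: Frame,
    topology: Topology,
    protein_selection: np.ndarray,
    tail_selections: list[np.ndarray],
    normal_axis: int = 2,
) -> np.ndarray:
    """In-plane unit vectors from the protein COM to each lipid free-tail COM."""
    protein_selection = np.asarray(protein_selection, dtype=int)
    if len(protein_selection) == 0 or not tail_selections:
        raise InvalidParameterError("protein and tail selections must be non-empty")
    masses = topology.masses
    pm = masses[protein_selection]
    pcom = (frame.positions[protein_selection] * pm[:, None]).sum(axis=0) / pm.sum()
    axes = [a for a in range(3) if a != normal_axis]
    out = np.zeros((len(tail_selections), 3))
    for i, sel in enumerate(tail_selections):
        sel = np.asarray(sel, dtype=int)
        tm = masses[sel]
        tcom = (frame.positions[sel] * tm[:, None]).sum(axis=0) / tm.sum()
        v = np.zeros(3)
        v[axes] = (tcom - pcom)[axes]
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            raise SingularGeometryError(f"tail COM {i} coincides with the protein COM in-plane")
        out[i] = v / norm
    return out


def build_pull_plan(
    magnitude: float,
    polar_angle: float,
    directions: np.ndarray,
    leaflet_normal: np.ndarray = (0.0, 0.0, -1.0),
) -> PullPlan:
    """Per-lipid force vectors F (cos(theta) e_r + sin(theta) n) plus the counterforce.

    ``leaflet_normal`` is the outward normal of the pulled leaflet (away from
    the bilayer midplane); the default -z corresponds to pulling the
    cytoplasmic (lower) leaflet's lipids.
    """
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if len(directions) == 0:
        raise InvalidParameterError("directions must be non-empty")
    if magnitude <= 0:
        raise InvalidParameterError("force magnitude must be > 0")
    if not 0.0 <= polar_angle <= 90.0:
        raise InvalidParameterError("polar angle must lie in [0, 90] degrees")
    n = np.asarray(leaflet_normal, dtype=float)
    n = n / np.linalg.norm(n)
    theta = np.radians(polar_angle)
    forces = magnitude * (np.cos(theta) * directions + np.sin(theta) * n)
    # in-plane components of a symmetric plan cancel among themselves; the
    # counterforce is purely vertical and cancels the summed vertical pull
    counter = -(forces @ n).sum() * n
    plan = PullPlan(
        directions=directions,
        magnitude=float(magnitude),
        polar_angle=float(polar_angle),
        forces=forces,
        counterforce=counter,
        leaflet_normal=n,
    )
    plan.validate()
    return plan


def leaflet_counterforce(plan: PullPlan) -> np.ndarray:
    """Counter-balancing force vector (pN) on the opposite leaflet's center of mass.

    Magnitude n F sin(theta), directed against the lipids' vertical pull.
    """
    return plan.counterforce
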