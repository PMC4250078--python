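"""Pairwise force evaluation for toy topologies.

Supplies the f_ij entering the potential part of the local stress tensor.
Harmonic bonds and Lennard-Jones pairs are central by construction; harmonic
three-body angle terms are reduced to central pair forces on the three
particle pairs (the central-force decomposition), which is exact for three
bodies and guarantees a symmetric stress contribution.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError, SingularGeometryError
from .system import Frame, PairForce, Topology
from .units import PN_PER_KJ_MOL_NM


def _harmonic_bond_forces(frame: Frame, top: Topology) -> list[PairForce]:
    out = []
    for (i, j), k, r0 in zip(top.bonds, top.bond_k, top.bond_r0):
        d = frame.separation(i, j)  # x_j - x_i, minimum image
        r = float(np.linalg.norm(d))
        if r == 0.0:
            raise SingularGeometryError(f"bonded pair ({i}, {j}) at zero separation")
        # V = k/2 (r - r0)^2 ; force on i points toward j when stretched
        f_i = k * (r - r0) * d / r
        out.append(PairForce(int(i), int(j), f_i))
    return out


def _lj_pair_forces(frame: Frame, top: Topology, cutoff: float) -> list[PairForce]:
    active = np.flatnonzero(top.lj_epsilon > 0)
    out = []
    for a in range(len(active)):
        for b in range(a + 1, len(active)):
            i, j = int(active[a]), int(active[b])
            if top.is_excluded(i, j):
                continue
            d = frame.separation(i, j)
            r = float(np.linalg.norm(d))
            if r == 0.0:
                raise SingularGeometryError(f"LJ pair ({i}, {j}) at zero separation")
            if r > cutoff:
                continue
            # Lorentz-Berthelot combination
            eps = np.sqrt(top.lj_epsilon[i] * top.lj_epsilon[j])  # kJ/mol
            sig = 0.5 * (top.lj_sigma[i] + top.lj_sigma[j])
            sr6 = (sig / r) ** 6
            # dV/dr = -24 eps (2 sr12 - sr6)/r ; force on i = -dV/dr * (-d/r)
            fmag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r * PN_PER_KJ_MOL_NM
            # repulsive (fmag>0): force on i points away from j, i.e. along -d
            out.append(PairForce(i, j, -fmag * d / r))
    return out


def angle_potential_forces(
    xi: np.ndarray, xj: np.ndarray, xk: np.ndarray, k_theta: float, theta0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Analytic forces of V = k/2 (theta - theta0)^2 with vertex at j.

    Returns (f_i, f_j, f_k, theta) in pN. Raises on collinear/coincident
    geometry where the angle gradient is singular.
    """
    u = xi - xj
    v = xk - xj
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise SingularGeometryError("angle term with coincident particles")
    uh, vh = u / nu, v / nv
    c = float(np.clip(uh @ vh, -1.0, 1.0))
    s = float(np.sqrt(max(1.0 - c * c, 0.0)))
    if s < 1e-12:
        raise SingularGeometryError("angle term at collinear geometry (gradient singular)")
    theta = float(np.arccos(c))
    dV = k_theta * (theta - theta0)
    # dtheta/dxi = (c*uh - vh) / (nu * s);  dtheta/dxk symmetric;  f = -dV * dtheta/dx
    f_i = -dV * (c * uh - vh) / (nu * s)
    f_k = -dV * (c * vh - uh) / (nv * s)
    f_j = -(f_i + f_k)
    return f_i, f_j, f_k, theta


def _central_decomposition(
    xi: np.ndarray, xj: np.ndarray, xk: np.ndarray, f_i: np.ndarray, f_j: np.ndarray, f_k: np.ndarray
) -> tuple[float, float, float]:
    """Scalar coefficients (a_ij, a_ik, a_jk) with f_i = a_ij r_ij + a_ik r_ik etc.

    Here r_ab = x_a - x_b. Solved in least squares; exact for any
    zero-net-force, zero-net-torque triple at non-collinear geometry.
    """
    r_ij = xi - xj
    r_ik = xi - xk
    r_jk = xj - xk
    A = np.zeros((9, 3))
    b = np.concatenate([f_i, f_j, f_k])
    A[0:3, 0] = r_ij
    A[0:3, 1] = r_ik
    A[3:6, 0] = -r_ij
    A[3:6, 2] = r_jk
    A[6:9, 1] = -r_ik
    A[6:9, 2] = -r_jk
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    return tuple(coef)


def evaluate_pair_forces(frame: Frame, topology: Topology, lj_cutoff: float = 1.6) -> list[PairForce]:
    """All central pair forces acting in one frame.

    One record per interacting pair, force on ``i`` from ``j`` in pN; the
    reverse force is the exact negation. Angle terms are decomposed into
    central forces on (i,j), (i,k), (j,k) so that the reconstructed
    per-particle forces match the analytic angle forces exactly.
    """
    if lj_cutoff <= 0:
        raise InvalidParameterError("LJ cutoff must be > 0")
    forces = _harmonic_bond_forces(frame, topology)
    forces.extend(_lj_pair_forces(frame, topology, lj_cutoff))
    for (i, j, k), kt, t0 in zip(topology.angles, topology.angle_k, topology.angle_theta0):
        i, j, k = int(i), int(j), int(k)
        # use minimum-image geometry around the vertex
        xj = frame.positions[j]
        xi = xj + frame.separation(j, i)
        xk = xj + frame.separation(j, k)
        f_i, f_j, f_k, _ = angle_potential_forces(xi, xj, xk, kt, t0)
        a_ij, a_ik, a_jk = _central_decomposition(xi, xj, xk, f_i, f_j, f_k)
        forces.append(PairForce(i, j, a_ij * (xi - xj)))
        forces.append(PairForce(i, k, a_ik * (xi - xk)))
        forces.append(PairForce(j, k, a_jk * (xj - xk)))
    return forces


def net_particle_forces(frame: Frame, topology: Topology, pair_forces: list[PairForce] | None = None) -> np.ndarray:
    """Per-particle net force (n, 3) reconstructed from pair records."""
    if pair_forces is None:
        pair_forces = evaluate_pair_forces(frame, topology)
    out = np.zeros((topology.n_particles, 3))
    for pf in pair_forces:
        out[pf.i] += pf.f
        out[pf.j] -= pf.f
    return out
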