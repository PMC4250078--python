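"""Gridded local (Cauchy) stress from particle trajectories.

The simulation box is tiled with uniform voxels and the time-averaged stress
tensor accumulated per voxel from two contributions:

* kinetic: -m v (x) v per particle, spread onto the 8 neighbouring voxels by
  cloud-in-cell (trilinear) weights;
* potential: f_ij (x) r_ij per interacting pair, spread along the i-j segment
  in proportion to the segment length inside each voxel.

Both weightings deposit unit total weight, so the voxel-volume-weighted sum
over the grid equals the global virial stress exactly — the conservation
property tested throughout. Sign convention is tension-positive:
pressure = -tr(sigma)/3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError, MissingVelocitiesError
from .forcefield import evaluate_pair_forces
from .grids import cic_deposit, grid_shape_for, segment_voxel_weights
from .system import Trajectory, minimum_image
from .units import BAR_PER_PN_NM2, PN_NM_PER_U_NM2_PS2

logger = logging.getLogger(__name__)

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class StressOptions:
    """Discretisation and filtering choices for the stress calculation."""

    spacing: float = 0.1  # nm
    kinetic_weighting: str = "cic"
    bond_weighting: str = "line"
    filter_width: float = 0.8  # nm, Gaussian standard deviation; 0 disables
    lj_cutoff: float = 1.6  # nm

    def __post_init__(self):
        if self.spacing <= 0:
            raise InvalidParameterError("spacing must be > 0")
        if self.filter_width < 0:
            raise InvalidParameterError("filter width must be >= 0")
        if self.kinetic_weighting != "cic" or self.bond_weighting != "line":
            raise InvalidParameterError(
                "supported weightings: kinetic='cic', bond='line'"
            )


@dataclass
class StressGrid:
    """3-D lattice of symmetric second-order stress tensors, units bar."""

    origin: np.ndarray  # nm, box corner
    spacing: np.ndarray  # nm per axis (exactly tiles the box)
    tensors: np.ndarray  # (nx, ny, nz, 3, 3), bar
    box: np.ndarray  # nm
    n_frames: int = 1
    units: str = "bar"

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if np.any(self.spacing <= 0):
            raise InvalidParameterError("voxel spacing must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def volume_integral(self) -> np.ndarray:
        """Sum over voxels of sigma * V_voxel, in pN*nm (global virial)."""
        return self.tensors.sum(axis=(0, 1, 2)) * self.voxel_volume / BAR_PER_PN_NM2

    def mean_tensor(self) -> np.ndarray:
        """Volume-averaged stress tensor, bar."""
        return self.tensors.mean(axis=(0, 1, 2))

    def pressure(self) -> float:
        """Box-averaged pressure -tr(sigma)/3, bar."""
        return float(-np.trace(self.mean_tensor()) / 3.0)

    def max_asymmetry(self) -> float:
        """Largest relative asymmetry |sigma - sigma^T| / scale over the grid."""
        anti = self.tensors - np.swapaxes(self.tensors, -1, -2)
        scale = np.abs(self.tensors).max() or 1.0
        return float(np.abs(anti).max() / scale)


def global_virial_stress(trajectory: Trajectory, lj_cutoff: float = 1.6) -> np.ndarray:
    """Box-averaged virial stress tensor in pN*nm (not divided by volume).

    Independent of any gridding: -sum m v(x)v + sum_pairs f_ij (x) r_ij,
    time-averaged. Used as the conservation oracle for the gridded field.
    """
    total = np.zeros((3, 3))
    for frame in trajectory:
        if frame.velocities is not None:
            v = frame.velocities
            total -= PN_NM_PER_U_NM2_PS2 * np.einsum(
                "n,ni,nj->ij", trajectory.topology.masses, v, v
            )
        for pf in evaluate_pair_forces(frame, trajectory.topology, lj_cutoff):
            r = minimum_image(frame.positions[pf.j] - frame.positions[pf.i], frame.box)
            total += np.outer(pf.f, r)
    return total / len(trajectory)


def compute_stress_grid(trajectory: Trajectory, options: StressOptions | None = None) -> StressGrid:
    """Time-averaged local stress tensor field (Eq.: kinetic + pairwise virial per voxel).

    Requires velocities for the kinetic term; a trajectory without velocities
    raises unless every frame genuinely has none *and* you accept a purely
    potential stress — in that case pass a trajectory whose frames carry
    explicit zero velocities.
    """
    options = options or StressOptions()
    box = trajectory.frames[0].box
    shape, spacing = grid_shape_for(box, options.spacing)
    acc = np.zeros((*shape, 9))

    topo = trajectory.topology
    masses = topo.masses
    has_interactions = len(topo.bonds) or len(topo.angles) or np.any(topo.lj_epsilon > 0)

    for frame in trajectory:
        if frame.velocities is None:
            raise MissingVelocitiesError(
                "kinetic stress term requires velocities on every frame"
            )
        v = frame.velocities
        kin = -PN_NM_PER_U_NM2_PS2 * masses[:, None, None] * np.einsum("ni,nj->nij", v, v)
        pos = np.mod(frame.positions, box)
        cic_deposit(pos, kin.reshape(-1, 9), shape, spacing, out=acc)
        if has_interactions:
            flat = acc.reshape(-1, 9)
            for pf in evaluate_pair_forces(frame, topo, options.lj_cutoff):
                r = minimum_image(frame.positions[pf.j] - frame.positions[pf.i], frame.box)
                dyad = np.outer(pf.f, r).reshape(9)
                start = np.mod(frame.positions[pf.i], box)
                for idx, w in segment_voxel_weights(start, r, shape, spacing):
                    lin = (idx[0] * shape[1] + idx[1]) * shape[2] + idx[2]
                    flat[lin] += w * dyad

    voxel_volume = float(np.prod(spacing))
    tensors = acc.reshape(*shape, 3, 3) * (
        BAR_PER_PN_NM2 / (voxel_volume * len(trajectory))
    )
    grid = StressGrid(
        origin=np.zeros(3),
        spacing=spacing,
        tensors=tensors,
        box=box.copy(),
        n_frames=len(trajectory),
    )
    if options.filter_width > 0:
        grid = gaussian_filter_field(grid, options.filter_width)
    return grid


def gaussian_filter_field(grid, width: float):
    """Component-wise periodic Gaussian convolution; ``width`` is the kernel sigma in nm.

    ``width=0`` returns the input unchanged. Works on :class:`StressGrid` and
    on the density grids from :mod:`mechanotrace.tractionmap` (anything with
    ``spacing`` and either ``tensors`` or ``values``).
    """
    if width < 0:
        raise InvalidParameterError("filter width must be >= 0")
    if width == 0:
        return grid
    sigma_vox = width / np.asarray(grid.spacing, dtype=float)
    if hasattr(grid, "tensors"):
        filtered = np.empty_like(grid.tensors)
        for a in range(3):
            for b in range(3):
                filtered[..., a, b] = ndimage.gaussian_filter(
                    grid.tensors[..., a, b], sigma=sigma_vox, mode="wrap"
                )
        return StressGrid(
            origin=grid.origin.copy(),
            spacing=grid.spacing.copy(),
            tensors=filtered,
            box=grid.box.copy(),
            n_frames=grid.n_frames,
            units=grid.units,
        )
    filtered = ndimage.gaussian_filter(grid.values, sigma=sigma_vox, mode="wrap")
    out = type(grid)(
        origin=grid.origin.copy(),
        spacing=grid.spacing.copy(),
        values=filtered,
        box=grid.box.copy(),
        selection=grid.selection,
        n_frames=grid.n_frames,
    )
    return out


def lateral_tension(grid: StressGrid, normal_axis: str | int = "z") -> float:
    """Membrane tension gamma = integral of (sigma_L - sigma_N) along the normal, pN/nm.

    sigma_L is the mean of the two lateral diagonal components, sigma_N the
    diagonal component along the membrane normal; tension-positive. A uniform
    field with lateral pressure P_L and normal pressure P_N over thickness L
    gives (P_N - P_L) * L.
    """
    ax = _AXES[normal_axis] if isinstance(normal_axis, str) else int(normal_axis)
    lat = [a for a in range(3) if a != ax]
    # profile along the normal: average over the two in-plane axes
    prof = grid.tensors.mean(axis=tuple(lat))  # (n_ax, 3, 3)
    off = np.abs(prof).sum(axis=(1, 2)) - np.abs(np.diagonal(prof, axis1=1, axis2=2)).sum(axis=1)
    diag = np.abs(np.diagonal(prof, axis1=1, axis2=2)).sum(axis=1)
    if off.sum() > diag.sum():
        logger.warning(
            "off-diagonal stress dominates the profile; lateral_tension may be meaningless"
        )
    sigma_l = 0.5 * (prof[:, lat[0], lat[0]] + prof[:, lat[1], lat[1]])
    sigma_n = prof[:, ax, ax]
    dz = grid.spacing[ax]
    return float(np.sum(sigma_l - sigma_n) * dz / BAR_PER_PN_NM2)
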