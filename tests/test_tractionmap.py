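import numpy as np
import pytest

from mechanotrace import (
    DensityGrid,
    Frame,
    StressGrid,
    Topology,
    Trajectory,
    compute_density_grid,
    export_surface,
    extract_isosurface,
    integrate_traction,
    read_surface,
    sample_traction,
)
from mechanotrace.errors import EmptySurfaceError, InvalidParameterError, OutOfDomainError
from mechanotrace.tractionmap import TractionSurface, integrate_abs_normal_traction


def _static_traj(positions, masses=None, box=(6, 6, 6)):
    n = len(positions)
    topo = Topology(
        masses=np.ones(n) if masses is None else np.asarray(masses, float),
        radii=np.zeros(n), elements=np.full(n, "C"), resids=np.arange(n),
        monomers=np.full(n, -1), sides=np.full(n, "none"), roles=np.full(n, "solvent"),
    )
    frame = Frame(0.0, np.asarray(positions, float), box=np.asarray(box, float))
    return Trajectory(topo, [frame])


def _gaussian_blob_density(box=6.4, spacing=0.1, width=1.0):
    n = int(box / spacing)
    x = (np.arange(n) + 0.5) * spacing - box / 2
    xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
    r2 = xx**2 + yy**2 + zz**2
    values = np.exp(-r2 / (2 * width**2))
    return DensityGrid(origin=np.zeros(3), spacing=np.full(3, spacing),
                       values=values, box=np.full(3, box))


def _uniform_stress(tensor, box=6.4, spacing=0.4):
    n = int(round(box / spacing))
    t = np.broadcast_to(np.asarray(tensor, float), (n, n, n, 3, 3)).copy()
    return StressGrid(origin=np.zeros(3), spacing=np.full(3, spacing),
                      tensors=t, box=np.full(3, box))


def _sphere_surface(level_radius=2.0, width=1.0, spacing=0.1):
    density = _gaussian_blob_density(spacing=spacing, width=width)
    level = float(np.exp(-(level_radius**2) / (2 * width**2)))
    return extract_isosurface(density, level=level)


class TestDensityGrid:
    def test_single_particle_mass_conserved(self):
        traj = _static_traj([[3.0, 3.0, 3.0]])
        grid = compute_density_grid(traj, np.array([0]), spacing=0.2, filter_width=0.2)
        assert grid.total_mass() == pytest.approx(1.0, rel=1e-6)

    def test_total_mass_independent_of_filter_width(self):
        traj = _static_traj([[2.0, 3.0, 3.0], [4.0, 3.0, 3.0]], masses=[2.0, 5.0])
        for w in (0.0, 0.2, 0.6):
            grid = compute_density_grid(traj, np.array([0, 1]), spacing=0.2, filter_width=w)
            assert grid.total_mass() == pytest.approx(7.0, rel=1e-6)

    def test_spherical_shell_peaks_at_shell_radius(self, rng):
        r_shell = 1.5
        dirs = rng.normal(size=(4000, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        pos = 3.0 + r_shell * dirs
        traj = _static_traj(pos)
        grid = compute_density_grid(traj, np.arange(4000), spacing=0.1, filter_width=0.1)
        ix = np.unravel_index(np.argmax(grid.values), grid.values.shape)
        center_of_peak = (np.array(ix) + 0.5) * grid.spacing
        assert np.linalg.norm(center_of_peak - 3.0) == pytest.approx(r_shell, abs=0.1)

    def test_empty_selection_rejected(self):
        traj = _static_traj([[3.0, 3.0, 3.0]])
        with pytest.raises(InvalidParameterError):
            compute_density_grid(traj, np.array([], dtype=int))


class TestIsosurface:
    def test_gaussian_blob_cut_gives_sphere_area(self):
        """Iso-level at radius 2 of a radial Gaussian yields area 4*pi*r^2 within 2%."""
        surface = _sphere_surface(level_radius=2.0)
        assert surface.area() == pytest.approx(4 * np.pi * 4.0, rel=0.02)

    def test_normals_point_away_from_density_maximum(self):
        surface = _sphere_surface()
        outward = surface.vertices - 3.2  # blob center
        dots = np.einsum("ij,ij->i", surface.normals, outward)
        assert np.all(dots > 0)
        assert np.allclose(np.linalg.norm(surface.normals, axis=1), 1.0, atol=1e-9)

    def test_level_outside_range_raises(self):
        density = _gaussian_blob_density()
        with pytest.raises(InvalidParameterError):
            extract_isosurface(density, level=2.0)
        with pytest.raises(InvalidParameterError):
            extract_isosurface(density, level=-0.1)

    def test_mesh_refinement_changes_area_below_percent(self):
        coarse = _sphere_surface(spacing=0.2)
        fine = _sphere_surface(spacing=0.1)
        assert abs(coarse.area() - fine.area()) / fine.area() <= 0.01


class TestSampleTraction:
    def test_hydrostatic_stress_gives_pure_normal_traction(self):
        surface = _sphere_surface()
        stress = _uniform_stress(-10.0 * np.eye(3))
        sample_traction(stress, surface)
        assert np.allclose(surface.t_normal, -10.0, atol=1e-9)
        assert np.allclose(surface.t_tangential, 0.0, atol=1e-9)

    def test_uniaxial_and_shear_closed_forms(self):
        # flat "surface": two triangles with normals along z
        verts = np.array([[1, 1, 2], [2, 1, 2], [2, 2, 2], [1, 2, 2]], dtype=float)
        faces = np.array([[0, 1, 2], [0, 2, 3]])
        normals = np.tile([0.0, 0.0, 1.0], (4, 1))
        surf = TractionSurface(vertices=verts, faces=faces, normals=normals)
        uniaxial = np.zeros((3, 3)); uniaxial[2, 2] = 5.0
        sample_traction(_uniform_stress(uniaxial), surf)
        assert np.allclose(surf.traction, [0, 0, 5.0])
        assert np.allclose(surf.t_normal, 5.0)
        assert np.allclose(surf.t_tangential, 0.0, atol=1e-12)
        # same plane under pure xz shear: traction is tangential
        shear = np.zeros((3, 3)); shear[0, 2] = shear[2, 0] = 3.0
        sample_traction(_uniform_stress(shear), surf)
        assert np.allclose(surf.traction, [3.0, 0, 0])
        assert np.allclose(surf.t_normal, 0.0, atol=1e-12)
        assert np.allclose(surf.t_tangential, 3.0)
        # with normals along x the zz-uniaxial stress produces no traction
        surf_x = TractionSurface(vertices=verts, faces=faces, normals=np.tile([1.0, 0, 0], (4, 1)))
        sample_traction(_uniform_stress(uniaxial), surf_x)
        assert np.allclose(surf_x.traction, 0.0)

    def test_decomposition_identity_everywhere(self, rng):
        surface = _sphere_surface()
        tensor = rng.normal(size=(3, 3)); tensor = (tensor + tensor.T) / 2
        sample_traction(_uniform_stress(tensor), surface)
        recomposed = surface.t_normal[:, None] * surface.normals + (
            surface.traction - surface.t_normal[:, None] * surface.normals
        )
        t_t_vec = surface.traction - surface.t_normal[:, None] * surface.normals
        assert np.abs(recomposed - surface.traction).max() <= 1e-9 * np.abs(surface.traction).max()
        dots = np.abs(np.einsum("ij,ij->i", t_t_vec, surface.normals))
        assert np.all(dots <= 1e-9 * np.linalg.norm(surface.traction, axis=1).max())

    def test_vertex_outside_grid_named_in_error(self):
        surface = _sphere_surface()
        stress = _uniform_stress(np.eye(3), box=2.0, spacing=0.5)
        with pytest.raises(OutOfDomainError, match="vertex"):
            sample_traction(stress, surface)


class TestIntegrateTraction:
    def test_closed_surface_under_uniform_stress_balances(self, rng):
        surface = _sphere_surface()
        tensor = rng.normal(size=(3, 3)); tensor = (tensor + tensor.T) / 2
        sample_traction(_uniform_stress(tensor), surface)
        net = integrate_traction(surface)
        scale = np.abs(tensor).max() * surface.area() / 10.0  # pN
        assert np.linalg.norm(net) <= 1e-6 * scale

    def test_hydrostatic_sphere_absolute_normal_force(self):
        surface = _sphere_surface(level_radius=2.0)
        sample_traction(_uniform_stress(-10.0 * np.eye(3)), surface)
        total = integrate_abs_normal_traction(surface)
        expected = 10.0 * 4 * np.pi * 4.0 / 10.0  # P * 4 pi r^2, bar nm^2 -> pN
        assert total == pytest.approx(expected, rel=0.02)

    def test_open_hemisphere_projects_to_disk_area(self):
        """Uniaxial sigma_zz = P over a hemisphere integrates to P * pi r^2 along z."""
        r = 2.0
        nth, nph = 40, 80
        th = np.linspace(0, np.pi / 2, nth)
        ph = np.linspace(0, 2 * np.pi, nph, endpoint=False)
        tt, pp = np.meshgrid(th, ph, indexing="ij")
        verts = np.column_stack([
            (r * np.sin(tt) * np.cos(pp)).ravel(),
            (r * np.sin(tt) * np.sin(pp)).ravel(),
            (r * np.cos(tt)).ravel(),
        ]) + 3.2
        idx = lambda i, j: i * nph + (j % nph)
        faces = []
        for i in range(nth - 1):
            for j in range(nph):
                faces.append([idx(i, j), idx(i + 1, j), idx(i + 1, j + 1)])
                faces.append([idx(i, j), idx(i + 1, j + 1), idx(i, j + 1)])
        normals = (verts - 3.2) / r
        surf = TractionSurface(vertices=verts, faces=np.array(faces), normals=normals)
        P = 5.0
        uniaxial = np.zeros((3, 3)); uniaxial[2, 2] = P
        sample_traction(_uniform_stress(uniaxial), surf)
        net = integrate_traction(surf)
        assert net[2] == pytest.approx(P * np.pi * r**2 / 10.0, rel=0.01)
        assert np.allclose(net[:2], 0.0, atol=1e-9)


class TestExport:
    @pytest.mark.parametrize("fmt", ["vtk", "ply"])
    def test_round_trip_preserves_everything(self, fmt, tmp_path):
        surface = _sphere_surface(spacing=0.2)
        sample_traction(_uniform_stress(np.diag([1.0, 2.0, -3.0])), surface)
        path = export_surface(surface, tmp_path / f"mesh.{fmt}")
        back = read_surface(path)
        assert np.array_equal(back.vertices, surface.vertices)
        assert np.array_equal(back.faces, surface.faces)
        assert np.array_equal(back.traction, surface.traction)
        assert np.array_equal(back.t_normal, surface.t_normal)
        assert np.array_equal(back.t_tangential, surface.t_tangential)

    def test_unknown_format_lists_supported(self, tmp_path):
        surface = _sphere_surface(spacing=0.2)
        sample_traction(_uniform_stress(np.eye(3)), surface)
        with pytest.raises(InvalidParameterError, match="vtk, ply"):
            export_surface(surface, tmp_path / "mesh.obj")

    def test_empty_surface_rejected(self, tmp_path):
        empty = TractionSurface(
            vertices=np.empty((0, 3)), faces=np.empty((0, 3), int), normals=np.empty((0, 3))
        )
        with pytest.raises(EmptySurfaceError):
            export_surface(empty, tmp_path / "mesh.vtk")
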