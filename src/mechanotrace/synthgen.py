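"""Synthetic input generators: oracle systems and the planted membrane-protein fixture.

Three families of inputs feed the analysis pipeline:

* equilibrium toy systems with analytically known stress (ideal gas for the
  kinetic term, a static harmonic dimer for the potential term);
* a coarse cylindrical five-fold membrane-protein fixture with planted
  ground truth: tightly-bound lipids holding a 0.4 nm P-N distance to
  labelled lysine-N sites, per-side hydrogen-bond census counts, and
  tail insertion into labelled hydrophobic cavities;
* exponential unbinding-time datasets drawn from the Arrhenius-Bell rate law
  k(f) = (1/tau0) exp(f x_beta / kT) at a list of pulling forces.

The fixture is a constructed ensemble, not dynamics: every frame is drawn
from the intended distribution directly, so planted quantities are exact by
construction and classifier tests recover them without simulation noise
beyond what is deliberately injected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .bellfit import UnbindingDataset
from .errors import InvalidParameterError, MinimumImageError
from .forcefield import evaluate_pair_forces  # noqa: F401  (module API: forces live here too)
from .system import Frame, Topology, Trajectory
from .units import KB_J_PER_K, PN_NM_PER_J, PN_NM_PER_U_NM2_PS2, thermal_energy

# ---------------------------------------------------------------- oracle systems


def gen_ideal_gas(
    n: int,
    temperature: float,
    box: tuple[float, float, float],
    n_frames: int = 1,
    seed: int = 0,
    mass: float = 18.0,
) -> Trajectory:
    """Non-interacting particles, uniform positions, Maxwell-Boltzmann velocities.

    The exact kinetic-stress oracle: the volume-averaged stress must equal
    -(N kT / V) I, i.e. the ideal-gas pressure, within sampling error.
    """
    box = np.asarray(box, dtype=float)
    if n <= 0 or temperature < 0 or np.any(box <= 0) or n_frames <= 0:
        raise InvalidParameterError("n, n_frames and box must be positive; temperature >= 0")
    rng = np.random.default_rng(seed)
    kT_u = KB_J_PER_K * temperature * PN_NM_PER_J / PN_NM_PER_U_NM2_PS2  # u nm^2/ps^2
    v_std = np.sqrt(kT_u / mass)
    topo = Topology(
        masses=np.full(n, mass),
        radii=np.full(n, 0.15),
        elements=np.full(n, "Ar"),
        resids=np.arange(n),
        monomers=np.full(n, -1),
        sides=np.full(n, "none"),
        roles=np.full(n, "solvent"),
    )
    frames = []
    for k in range(n_frames):
        pos = rng.uniform(0.0, box, size=(n, 3))
        vel = rng.normal(0.0, v_std, size=(n, 3)) if temperature > 0 else np.zeros((n, 3))
        frames.append(Frame(time=float(k), positions=pos, box=box, velocities=vel))
    return Trajectory(topology=topo, frames=frames, frame_spacing=1.0)


def gen_harmonic_dimer(
    separation: float,
    stiffness: float = 100.0,
    rest_length: float = 1.0,
    box: tuple[float, float, float] = (10.0, 10.0, 10.0),
) -> Trajectory:
    """Two bonded particles along x at the given separation, zero velocities.

    The potential-stress oracle: the box-integrated stress equals the virial
    dyad f (x) r = k (separation - rest_length) * separation in the xx
    component (tension-positive for a stretched bond) and zero elsewhere.
    """
    box = np.asarray(box, dtype=float)
    if separation <= 0 or rest_length <= 0 or np.any(box <= 0):
        raise InvalidParameterError("separation, rest_length and box must be > 0")
    if separation > box.min() / 2:
        raise MinimumImageError("separation exceeds half the smallest box length")
    topo = Topology(
        masses=np.array([10.0, 10.0]),
        radii=np.array([0.15, 0.15]),
        elements=np.array(["C", "C"]),
        resids=np.array([0, 1]),
        monomers=np.array([-1, -1]),
        sides=np.array(["none", "none"]),
        roles=np.array(["solvent", "solvent"]),
        bonds=np.array([[0, 1]]),
        bond_k=np.array([stiffness]),
        bond_r0=np.array([rest_length]),
    )
    center = box / 2
    pos = np.array(
        [center - [separation / 2, 0, 0], center + [separation / 2, 0, 0]]
    )
    frame = Frame(time=0.0, positions=pos, box=box, velocities=np.zeros((2, 3)))
    return Trajectory(topology=topo, frames=[frame], frame_spacing=1.0)


# ---------------------------------------------------------------- fixture


@dataclass
class FixtureConfig:
    """Parameters of the coarse membrane-protein fixture.

    Defaults are the study conditions the analysis targets: a five-fold
    protein with 10 tightly-bound lipids (2 per monomer), 8 of them inserting
    the shorter tail, a planted per-side hydrogen-bond census of 40
    (cytoplasmic) and 21 (periplasmic) lipids of which 85% of the cytoplasmic
    ones bond a lysine, and a bound-state P-N distance of median 0.4 nm with
    11.04 pm Gaussian spread (26 pm full width at half maximum).
    """

    monomers: int = 5
    lipids_per_leaflet: int = 50
    n_tight: int = 10
    n_short_inserted: int = 8
    hbond_cytoplasmic: int = 40
    hbond_periplasmic: int = 21
    lysine_fraction: float = 0.85
    pn_median: float = 0.4  # nm
    pn_sigma: float = 0.01104  # nm (= 11.04 pm)
    n_frames: int = 500
    frame_spacing: float = 100.0  # ps
    box: tuple[float, float, float] = (12.0, 12.0, 10.0)

    def __post_init__(self):
        if self.monomers < 1 or self.lipids_per_leaflet < 1 or self.n_frames < 1:
            raise InvalidParameterError("monomers, lipids_per_leaflet, n_frames must be >= 1")
        if self.n_tight % self.monomers:
            raise InvalidParameterError("n_tight must distribute evenly over monomers")
        if self.n_tight // self.monomers > 2:
            raise InvalidParameterError("at most 2 tightly-bound lipids per monomer (one per lysine)")
        if not 0 <= self.n_short_inserted <= self.n_tight:
            raise InvalidParameterError("n_short_inserted must be between 0 and n_tight")
        if self.hbond_cytoplasmic > self.lipids_per_leaflet or self.hbond_periplasmic > self.lipids_per_leaflet:
            raise InvalidParameterError("planted H-bond counts exceed available lipids")
        n_lysine_bonded = round(self.lysine_fraction * self.hbond_cytoplasmic)
        if n_lysine_bonded < self.n_tight:
            raise InvalidParameterError("lysine-bonded count smaller than tightly-bound count")
        if self.pn_sigma <= 0 or self.pn_median <= 0:
            raise InvalidParameterError("pn_median and pn_sigma must be > 0")

    @property
    def n_lysine_bonded(self) -> int:
        return round(self.lysine_fraction * self.hbond_cytoplasmic)


@dataclass
class PlantedTruth:
    """Ground truth planted into the fixture, for recovery tests."""

    lipid_resids: list[int]
    tight: dict[int, bool]
    inserted_tail: dict[int, str]  # 'short' | 'long' | 'none'
    side: dict[int, str]
    monomer: dict[int, int]  # tight lipids -> monomer id, else -1
    bound_intervals: dict[int, list[tuple[float, float]]]  # resid -> [(t0, t1)] ns
    hbond_counts: dict[str, int]
    lysine_fraction: float
    pore_ring_indices: list[int]
    span_ns: float

    def n_tight(self) -> int:
        return sum(self.tight.values())

    def n_short_inserted(self) -> int:
        return sum(1 for r, t in self.inserted_tail.items() if self.tight[r] and t == "short")

    def validate(self, config: FixtureConfig) -> None:
        if self.n_tight() != config.n_tight:
            raise InvalidParameterError("planted tight count does not match config")
        for ivals in self.bound_intervals.values():
            for t0, t1 in ivals:
                if not (0.0 <= t0 <= t1 <= self.span_ns + 1e-9):
                    raise InvalidParameterError("bound interval outside trajectory span")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["tight"] = {str(k): v for k, v in self.tight.items()}
        payload["inserted_tail"] = {str(k): v for k, v in self.inserted_tail.items()}
        payload["side"] = {str(k): v for k, v in self.side.items()}
        payload["monomer"] = {str(k): v for k, v in self.monomer.items()}
        payload["bound_intervals"] = {str(k): v for k, v in self.bound_intervals.items()}
        path.write_text(json.dumps(payload, indent=1))
        return path


class _TopologyBuilder:
    def __init__(self):
        self.cols = {k: [] for k in ("masses", "radii", "elements", "resids", "monomers", "sides", "roles")}
        self.positions = []

    def add(self, pos, mass, radius, element, resid, monomer, side, role):
        self.positions.append(np.asarray(pos, dtype=float))
        for key, val in zip(
            self.cols, (mass, radius, element, resid, monomer, side, role)
        ):
            self.cols[key].append(val)
        return len(self.positions) - 1

    def topology(self) -> Topology:
        return Topology(
            masses=np.array(self.cols["masses"]),
            radii=np.array(self.cols["radii"]),
            elements=np.array(self.cols["elements"]),
            resids=np.array(self.cols["resids"]),
            monomers=np.array(self.cols["monomers"]),
            sides=np.array(self.cols["sides"]),
            roles=np.array(self.cols["roles"]),
        )


def _unit(v):
    return v / np.linalg.norm(v)


def gen_membrane_protein_fixture(
    config: FixtureConfig | None = None, seed: int = 1
) -> tuple[Trajectory, PlantedTruth]:
    """Coarse five-fold membrane-protein fixture with planted binding truth.

    Geometry (static protein, constructed lipid ensembles per frame):

    * protein: cylinder of radius ~1.5 nm about the box axis; per monomer two
      cytoplasmic lysine-N sites, two cytoplasmic polar-O sites, five
      periplasmic polar-O sites, two mid-membrane hydrophobic cavity sites,
      one pore-ring site, and body particles for the density field;
    * tightly-bound lipids: P held at N(median, sigma) from an assigned
      lysine, one acceptor-O permanently inside the hydrogen-bond cutoff, one
      tail's terminal particles inside an assigned cavity;
    * census lipids: acceptor-O at a fixed 0.30 nm from an assigned protein
      polar site (lysine or not) with randomized direction, tails away from
      all cavities;
    * free lipids: lateral random walk at radius >= 3 nm, never within the
      hydrogen-bond cutoff of the protein.
    """
    config = config or FixtureConfig()
    rng = np.random.default_rng(seed)
    box = np.asarray(config.box, dtype=float)
    cx, cy, _ = box / 2
    z_mid = box[2] / 2
    z_cyto_head, z_peri_head = z_mid - 1.4, z_mid + 1.4
    z_cavity = z_mid - 0.4
    r_protein = 1.5

    b = _TopologyBuilder()
    lysine_sites: list[tuple[int, int]] = []  # (particle index, monomer)
    cyto_polar_sites: list[int] = []
    peri_polar_sites: list[int] = []
    cavity_sites: dict[int, list[int]] = {}
    pore_ring: list[int] = []

    def ring_pos(radius, angle, z):
        return np.array([cx + radius * np.cos(angle), cy + radius * np.sin(angle), z])

    resid = 0  # protein occupies resid 0
    for m in range(config.monomers):
        phi = 2 * np.pi * m / config.monomers
        for dphi in (-0.25, 0.25):
            lysine_sites.append(
                (b.add(ring_pos(r_protein, phi + dphi, z_cyto_head), 14.0, 0.16, "N", resid, m, "cytoplasmic", "lysine-N"), m)
            )
        for dphi in (-0.5, 0.5):
            cyto_polar_sites.append(
                b.add(ring_pos(r_protein, phi + dphi, z_cyto_head), 16.0, 0.15, "O", resid, m, "cytoplasmic", "protein")
            )
        for dphi in (-0.5, -0.25, 0.0, 0.25, 0.5):
            peri_polar_sites.append(
                b.add(ring_pos(r_protein, phi + dphi, z_peri_head), 16.0, 0.15, "O", resid, m, "periplasmic", "protein")
            )
        cavity_sites[m] = [
            b.add(ring_pos(r_protein + 0.05, phi + dphi, z_cavity), 12.0, 0.17, "C", resid, m, "none", "protein")
            for dphi in (-0.25, 0.25)
        ]
        pore_ring.append(b.add(ring_pos(0.8, phi, z_mid), 12.0, 0.17, "C", resid, m, "none", "protein"))
        for zb in np.linspace(z_mid - 1.2, z_mid + 1.2, 6):
            b.add(ring_pos(1.0, phi, zb), 12.0, 0.17, "C", resid, m, "none", "protein")
            b.add(ring_pos(1.3, phi + 0.4, zb), 12.0, 0.17, "C", resid, m, "none", "protein")

    protein_n = len(b.positions)

    # ---- lipid bookkeeping -------------------------------------------------
    n_social = config.n_lysine_bonded - config.n_tight
    n_other_cyto = config.hbond_cytoplasmic - config.n_lysine_bonded
    n_free_cyto = config.lipids_per_leaflet - config.hbond_cytoplasmic
    n_free_peri = config.lipids_per_leaflet - config.hbond_periplasmic
    if config.hbond_periplasmic > len(peri_polar_sites):
        raise InvalidParameterError("not enough periplasmic sites for the planted census")

    span_ns = config.n_frames * config.frame_spacing / 1000.0
    truth = PlantedTruth(
        lipid_resids=[], tight={}, inserted_tail={}, side={}, monomer={},
        bound_intervals={}, hbond_counts={"cytoplasmic": config.hbond_cytoplasmic, "periplasmic": config.hbond_periplasmic},
        lysine_fraction=config.n_lysine_bonded / config.hbond_cytoplasmic if config.hbond_cytoplasmic else 0.0,
        pore_ring_indices=pore_ring, span_ns=span_ns,
    )

    # per-lipid static plan; per-frame stochastic refinements happen below
    plans = []  # dicts describing each lipid

    def new_lipid(side):
        nonlocal resid
        resid += 1
        truth.lipid_resids.append(resid)
        truth.side[resid] = side
        truth.tight[resid] = False
        truth.inserted_tail[resid] = "none"
        truth.monomer[resid] = -1
        truth.bound_intervals[resid] = []
        return resid

    positions0 = np.array(b.positions)

    # tightly-bound lipids: one per lysine, first n_tight lysines
    per_monomer = config.n_tight // config.monomers
    tight_lysines = [ls for m in range(config.monomers) for ls in
                     [s for s in lysine_sites if s[1] == m][:per_monomer]]
    for k, (lys_idx, m) in enumerate(tight_lysines):
        rid = new_lipid("cytoplasmic")
        truth.tight[rid] = True
        truth.monomer[rid] = m
        tail = "short" if k < config.n_short_inserted else "long"
        truth.inserted_tail[rid] = tail
        truth.bound_intervals[rid] = [(0.0, span_ns)]
        cavity = cavity_sites[m][k % len(cavity_sites[m])]
        u = _unit(positions0[lys_idx][:2] - np.array([cx, cy]))
        plans.append(dict(kind="tight", resid=rid, lysine=lys_idx, cavity=cavity, u=u, tail=tail))

    # census lipids bonded to lysines without tail insertion ("social")
    all_lysines = [s[0] for s in lysine_sites]
    for k in range(n_social):
        rid = new_lipid("cytoplasmic")
        lys_idx = all_lysines[k % len(all_lysines)]
        plans.append(dict(kind="census", resid=rid, site=lys_idx, z_head=z_cyto_head, slot=k))
    # census lipids bonded to non-lysine cytoplasmic polar sites
    for k in range(n_other_cyto):
        rid = new_lipid("cytoplasmic")
        site = cyto_polar_sites[k % len(cyto_polar_sites)]
        plans.append(dict(kind="census", resid=rid, site=site, z_head=z_cyto_head, slot=k))
    # periplasmic census lipids
    for k in range(config.hbond_periplasmic):
        rid = new_lipid("periplasmic")
        plans.append(dict(kind="census", resid=rid, site=peri_polar_sites[k], z_head=z_peri_head, slot=k))
    # free lipids
    for side, count, z_head in (
        ("cytoplasmic", n_free_cyto, z_cyto_head),
        ("periplasmic", n_free_peri, z_peri_head),
    ):
        for _ in range(count):
            rid = new_lipid(side)
            plans.append(dict(
                kind="free", resid=rid, z_head=z_head,
                angle=rng.uniform(0, 2 * np.pi), radius=rng.uniform(3.2, 4.8),
            ))

    # ---- build topology rows for every lipid -------------------------------
    lipid_particle_slices = {}
    for plan in plans:
        rid = plan["resid"]
        side = truth.side[rid]
        start = len(b.positions)
        origin = np.zeros(3)  # placeholder; per-frame positions overwrite
        b.add(origin, 31.0, 0.19, "P", rid, -1, side, "lipid-head-P")
        b.add(origin, 16.0, 0.15, "O", rid, -1, side, "lipid-head-N-acceptor-O")
        b.add(origin, 16.0, 0.15, "O", rid, -1, side, "lipid-head-N-acceptor-O")
        for _ in range(2):
            b.add(origin, 14.0, 0.2, "C", rid, -1, side, "lipid-tail-short")
        for _ in range(3):
            b.add(origin, 14.0, 0.2, "C", rid, -1, side, "lipid-tail-long")
        lipid_particle_slices[rid] = slice(start, len(b.positions))

    topo = b.topology()
    n_total = topo.n_particles

    # ---- per-frame positions ----------------------------------------------
    z_sign = {"cytoplasmic": -1.0, "periplasmic": 1.0}
    frames = []
    free_state = {p["resid"]: (p["angle"], p["radius"]) for p in plans if p["kind"] == "free"}
    for fidx in range(config.n_frames):
        pos = np.empty((n_total, 3))
        pos[:protein_n] = positions0[:protein_n]
        for plan in plans:
            rid = plan["resid"]
            sl = lipid_particle_slices[rid]
            side = truth.side[rid]
            sgn = z_sign[side]
            if plan["kind"] == "tight":
                lys = positions0[plan["lysine"]]
                u3 = np.array([plan["u"][0], plan["u"][1], 0.0])
                d = rng.normal(config.pn_median, config.pn_sigma)
                p_head = lys + d * u3
                o1 = lys + 0.28 * u3
                o2 = p_head + 0.12 * u3
                cav = positions0[plan["cavity"]]
                jitter = rng.normal(0, 0.05, size=(5, 3))
                if plan["tail"] == "short":
                    t_short = cav + np.clip(jitter[:2], -0.12, 0.12)
                    t_long = np.stack([p_head + (k + 1) * 0.35 * u3 + [0, 0, sgn * 0.1 * (k + 1)] for k in range(3)])
                else:
                    t_long = np.stack([cav + np.clip(jitter[2 + k], -0.12, 0.12) for k in range(3)])
                    t_short = np.stack([p_head + (k + 1) * 0.35 * u3 + [0, 0, sgn * 0.1 * (k + 1)] for k in range(2)])
            elif plan["kind"] == "census":
                site = positions0[plan["site"]]
                u = _unit(site[:2] - np.array([cx, cy]))
                u3 = np.array([u[0], u[1], 0.0])
                # fixed 0.30 nm bond distance, randomized direction in the
                # outward hemisphere (keeps the census exact per frame)
                psi = 0.45 * np.sin(2.1 * plan["slot"] + fidx * 0.013)
                tilt = rng.normal(0.0, 0.15)
                dvec = np.cos(psi) * u3 + np.sin(psi) * np.array([0, 0, 1.0])
                dvec = _unit(dvec + tilt * np.array([-u3[1], u3[0], 0.0]))
                o1 = site + 0.30 * dvec
                p_head = o1 + 0.15 * u3
                o2 = p_head + 0.12 * u3
                base = p_head + 0.3 * u3
                t_short = np.stack([base + (k + 1) * 0.3 * u3 for k in range(2)])
                t_long = np.stack([base + (k + 1) * 0.3 * u3 + [0, 0, sgn * 0.08 * (k + 1)] for k in range(3)])
            else:  # free random walker, kept clear of the protein
                ang, rad = free_state[rid]
                ang += rng.normal(0, 0.08)
                rad = float(np.clip(rad + rng.normal(0, 0.12), 3.0, 4.9))
                free_state[rid] = (ang, rad)
                u3 = np.array([np.cos(ang), np.sin(ang), 0.0])
                p_head = np.array([cx, cy, plan["z_head"]]) + rad * u3
                o1 = p_head - 0.15 * u3
                o2 = p_head + 0.12 * u3
                t_short = np.stack([p_head + (k + 1) * 0.3 * u3 for k in range(2)])
                t_long = np.stack([p_head + (k + 1) * 0.3 * u3 + [0, 0, sgn * 0.08 * (k + 1)] for k in range(3)])
            pos[sl] = np.vstack([p_head, o1, o2, t_short, t_long])
        frames.append(
            Frame(
                time=fidx * config.frame_spacing,
                positions=pos,
                box=box,
                velocities=np.zeros((n_total, 3)),
            )
        )

    traj = Trajectory(topology=topo, frames=frames, frame_spacing=config.frame_spacing)
    truth.validate(config)
    return traj, truth


# ---------------------------------------------------------------- P-N traces


@dataclass
class PNTraces:
    """Two-state telegraph P-N distance traces, nm, with the bound mask."""

    distances: np.ndarray  # (n_traces, n_frames)
    bound: np.ndarray  # bool mask, same shape
    times: np.ndarray  # ps

    def pooled_bound_distances(self) -> np.ndarray:
        return self.distances[self.bound]


def gen_pn_traces(
    n_traces: int = 10,
    median: float = 0.4,
    sigma: float = 0.01104,
    occupancy: float = 1.0,
    n_frames: int = 50_000,
    dt: float = 5.0,
    seed: int = 1,
    unbound_floor: float = 0.6,
) -> PNTraces:
    """Telegraph traces: Gaussian about the median while bound, diffusing above a floor while not.

    ``occupancy`` sets the stationary bound fraction of a two-state Markov
    chain (mean bound dwell 200 frames); 1 and 0 are the degenerate always-
    bound / never-bound cases.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise InvalidParameterError("occupancy must be in [0, 1]")
    if sigma <= 0 or median <= 0 or n_traces <= 0 or n_frames <= 0:
        raise InvalidParameterError("median, sigma, n_traces, n_frames must be > 0")
    rng = np.random.default_rng(seed)
    bound = np.zeros((n_traces, n_frames), dtype=bool)
    if occupancy >= 1.0:
        bound[:] = True
    elif occupancy > 0.0:
        p_bu = 1.0 / 200.0
        p_ub = occupancy * p_bu / (1.0 - occupancy)
        p_ub = min(p_ub, 1.0)
        state = rng.random(n_traces) < occupancy
        for t in range(n_frames):
            bound[:, t] = state
            flip = rng.random(n_traces)
            state = np.where(state, flip >= p_bu, flip < p_ub)
    dist = np.empty((n_traces, n_frames))
    dist[bound] = rng.normal(median, sigma, size=int(bound.sum()))
    n_unbound = int((~bound).sum())
    if n_unbound:
        steps = rng.normal(0.0, 0.02, size=n_unbound)
        walk = unbound_floor + 0.2 + np.abs(np.cumsum(steps) % 1.0 - 0.5)  # stays > floor
        dist[~bound] = walk
    return PNTraces(distances=dist, bound=bound, times=np.arange(n_frames) * dt)


# ---------------------------------------------------------------- unbinding times


def bell_rate(force: float, tau0: float, xbeta_pm: float, temperature: float) -> float:
    """Arrhenius-Bell dissociation rate k(f) = (1/tau0) exp(f x_beta / kT), 1/ns.

    ``force`` in pN, ``tau0`` in ns, ``xbeta_pm`` in pm.
    """
    kT = thermal_energy(temperature)  # pN nm
    return np.exp(force * xbeta_pm * 1e-3 / kT) / tau0


def gen_unbinding_times(
    forces: list[float] = (530.0, 660.0, 830.0, 910.0, 1000.0),
    tau0: float = 441.0,
    xbeta: float = 35.0,
    temperature: float = 310.15,
    n_lipids: int = 10,
    n_reps: int = 5,
    seed: int = 1,
) -> list[UnbindingDataset]:
    """Exponential unbinding-event times from the Bell rate law, one dataset per force.

    ``tau0`` in ns, ``xbeta`` in pm. Each dataset holds n_lipids * n_reps
    observed events (no censoring at these forces).
    """
    if tau0 <= 0 or xbeta <= 0:
        raise InvalidParameterError("tau0 and xbeta must be > 0")
    if any(f < 0 for f in forces):
        raise InvalidParameterError("forces must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for f in forces:
        k = bell_rate(f, tau0, xbeta, temperature)
        times = rng.exponential(1.0 / k, size=n_lipids * n_reps)
        reps = np.repeat(np.arange(n_reps), n_lipids)
        out.append(
            UnbindingDataset(
                force=float(f),
                times=times,
                censored=np.zeros(len(times), dtype=bool),
                n_at_risk=len(times),
                replicate=reps,
            )
        )
    return out
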