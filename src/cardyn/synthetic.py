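"""Synthetic trajectory generation.

Two kinds of inputs are produced here:

* A coarse-grained *coupled-pendulum receptor*: one bead per structural
  blob (antigen-binding head AB, signaling tail SI) and short bead chains
  for the hinge (HI), transmembrane (TM) and costimulatory (CS) linkers,
  spanning a membrane slab. The TM beads are harmonically anchored inside
  the slab; the AB and SI blobs are restrained toward their rest positions
  with an effective pendulum stiffness (``k_HI`` and ``k_CS``) representing
  the torque the adjacent linker exerts on its bob, and half-harmonic walls
  keep extra- and intracellular beads out of the slab. Overdamped Langevin
  (Euler–Maruyama) dynamics then samples the stationary ensemble. The apo
  preset has a soft extracellular hinge and a stiff intracellular linker
  (wide AB sampling, narrow SI sampling); the holo preset adds an antigen
  bead tethered to a fixed extracellular site and swaps the stiffness
  contrast, so sampling width migrates to the intracellular side — the
  binding-induced domain-dynamics switch the analysis pipeline must
  recover. Units are reduced (kT = 1, γ = 1, lengths Å-like).

* Deterministic atomistic *fixtures* for unit tests: ideal helices and
  strands built at exact (φ, ψ), rigid-motion copies of a base frame with
  optional seeded noise, and membrane pseudo-atom lattices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, NumericalError
from .model import AtomRecord, DomainMap, Frame, Trajectory

__all__ = [
    "SimulationConfig", "BeadTopology", "FixtureSpec", "preset_config",
    "build_receptor_model", "simulate", "domain_map_for", "make_fixture",
    "make_helix", "make_strand", "make_rigid_copies", "make_membrane_slab",
]

STABILITY_LIMIT = 0.1  # dt * k_max / gamma must stay below this


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one coupled-pendulum simulation (reduced units)."""

    state: str  # "apo" | "holo"
    seed: int
    n_steps: int = 60_000
    dt: float = 0.01
    friction: float = 1.0
    kT: float = 1.0
    stride: int = 100
    # per-role stiffness (energy/Å² for bonds and anchors, energy/rad² for angles)
    k_HI: float = 0.05  # effective pendulum stiffness on the AB blob
    k_CS: float = 1.0  # effective pendulum stiffness on the SI blob
    k_anchor_AG: float = 2.0  # antigen tether (holo only)
    k_bond: float = 2.0
    k_angle: float = 1.0
    k_anchor_TM: float = 5.0
    k_wall: float = 5.0
    # geometry
    n_HI: int = 4
    n_CS: int = 4
    n_TM: int = 9
    bead_spacing: float = 4.0  # Å, linker bond rest length
    slab_halfwidth: float = 15.0  # Å
    # holo only: the antigen tether bends the head toward the membrane,
    # displacing the AB/AG rest position laterally and downward (Å)
    bend_lateral: float = 8.0
    bend_drop: float = 10.0
    include_membrane: bool = True
    membrane_nx: int = 6
    membrane_ny: int = 6
    membrane_spacing: float = 8.0  # Å

    def __post_init__(self):
        if self.state not in ("apo", "holo"):
            raise ConfigError(f"unknown state '{self.state}' (expected apo or holo)")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.dt * self.k_max / self.friction >= STABILITY_LIMIT:
            raise ConfigError(
                f"stability bound violated: dt*k_max/gamma = "
                f"{self.dt * self.k_max / self.friction:.3f} >= {STABILITY_LIMIT}")

    @property
    def k_max(self) -> float:
        ks = [self.k_HI, self.k_CS, self.k_bond, self.k_angle,
              self.k_anchor_TM, self.k_wall]
        if self.state == "holo":
            ks.append(self.k_anchor_AG)
        return max(ks)


@dataclass
class BeadTopology:
    """Bead-spring topology: roles, rest positions, bonds, angles, anchors, walls."""

    roles: list[str]  # per bead: AG | AB | HI | TM | CS | SI
    rest_positions: np.ndarray  # (n, 3) Å
    bonds: list[tuple[int, int, float, float]]  # i, j, k_bond, r0
    angles: list[tuple[int, int, int, float, float]]  # i, j, k (vertex j), k_angle, theta0
    anchors: list[tuple[int, np.ndarray, float]]  # bead, site, k_anchor
    walls: list[tuple[int, float, float, float]]  # bead, sign, z_bound, k_wall

    @property
    def n_beads(self) -> int:
        return len(self.roles)


def preset_config(state: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Study-condition presets for the two receptor states.

    apo: no antigen bead, soft extracellular hinge (low ``k_HI``), stiff
    intracellular linker (high ``k_CS``) — wide AB sampling, narrow SI
    sampling. holo: antigen bead tethered to a fixed extracellular site,
    stiff hinge, soft intracellular linker — the reverse. The default
    stiffness contrast (20-fold) programs a ≥4-fold ratio in equilibrium
    center-cloud covariance trace for both the AB and the SI contrast.
    """
    if state == "apo":
        base = dict(state="apo", seed=seed, k_HI=0.05, k_CS=1.0)
    elif state == "holo":
        base = dict(state="holo", seed=seed, k_HI=1.0, k_CS=0.05)
    else:
        raise ConfigError(f"unknown state '{state}' (expected apo or holo)")
    base.update(overrides)
    return SimulationConfig(**base)


def build_receptor_model(config: SimulationConfig) -> BeadTopology:
    """Deterministic bead topology for one state.

    Chain order (and residue numbering in the emitted trajectory):
    AB, HI beads, TM beads, CS beads, SI, then AG last in the holo state.
    TM beads span z ∈ [−halfwidth, +halfwidth]; all bonds are at rest length
    in the initial configuration.
    """
    hw = config.slab_halfwidth
    sp = config.bead_spacing
    if config.n_TM < 2:
        raise ConfigError("need at least 2 TM beads to span the slab")
    tm_spacing = 2 * hw / (config.n_TM - 1)
    roles: list[str] = []
    zs: list[float] = []
    # extracellular, top down: AB then HI
    roles.append("AB")
    zs.append(hw + sp * (config.n_HI + 1))
    for i in range(config.n_HI):
        roles.append("HI")
        zs.append(hw + sp * (config.n_HI - i))
    for i in range(config.n_TM):
        roles.append("TM")
        zs.append(hw - i * tm_spacing)
    for i in range(config.n_CS):
        roles.append("CS")
        zs.append(-hw - sp * (i + 1))
    roles.append("SI")
    zs.append(-hw - sp * (config.n_CS + 1))
    n_chain = len(roles)
    if config.state == "holo":
        roles.append("AG")
        zs.append(zs[0] + sp)
    # the chain traces a gentle helix (radius 0.8 Å) so no rest configuration —
    # of the whole receptor or of any domain — is collinear, and the anchored
    # TM fit determines all three rotations
    rest = np.array([[0.8 * math.cos(2.4 * i), 0.8 * math.sin(2.4 * i), z]
                     for i, z in enumerate(zs)])
    if config.state == "holo":
        # bound head rests bent toward the membrane: the antigen tether on the
        # target cell shortens the head-to-anchor distance
        bend = np.array([config.bend_lateral, 0.0, -config.bend_drop])
        rest[0] += bend
        rest[n_chain] = rest[0] + [sp, 0.0, 0.0]  # AG alongside the bent head

    bonds = []
    for i in range(n_chain - 1):
        r0 = float(np.linalg.norm(rest[i + 1] - rest[i]))
        bonds.append((i, i + 1, config.k_bond, r0))
    # rest angles taken from the built geometry, so the initial configuration
    # is a true energy minimum
    angles = []
    for i in range(n_chain - 2):
        u = rest[i] - rest[i + 1]
        v = rest[i + 2] - rest[i + 1]
        cos_t = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
        theta0 = math.acos(max(-1.0, min(1.0, cos_t)))
        angles.append((i, i + 1, i + 2, config.k_angle, theta0))
    anchors: list[tuple[int, np.ndarray, float]] = []
    walls: list[tuple[int, float, float, float]] = []
    for i, role in enumerate(roles[:n_chain]):
        if role == "TM":
            anchors.append((i, rest[i].copy(), config.k_anchor_TM))
        elif role == "AB":
            anchors.append((i, rest[i].copy(), config.k_HI))
            walls.append((i, +1.0, hw, config.k_wall))
        elif role == "SI":
            anchors.append((i, rest[i].copy(), config.k_CS))
            walls.append((i, -1.0, -hw, config.k_wall))
        elif role == "HI":
            walls.append((i, +1.0, hw, config.k_wall))
        elif role == "CS":
            walls.append((i, -1.0, -hw, config.k_wall))
    if config.state == "holo":
        iag = n_chain  # AG bead index
        r0 = float(np.linalg.norm(rest[iag] - rest[0]))
        bonds.append((0, iag, config.k_bond, r0))
        anchors.append((iag, rest[iag].copy(), config.k_anchor_AG))
        walls.append((iag, +1.0, hw, config.k_wall))
    topo = BeadTopology(roles=roles, rest_positions=rest, bonds=bonds,
                        angles=angles, anchors=anchors, walls=walls)
    # sanity: no bond crosses a wall at rest
    for i, j, _, _ in bonds:
        zi, zj = rest[i, 2], rest[j, 2]
        if (zi > hw) != (zj > hw) and roles[i] != "TM" and roles[j] != "TM":
            raise ConfigError("bond crosses the slab boundary at rest")
    return topo


def _forces(x: np.ndarray,
            bond_i, bond_j, bond_k, bond_r0,
            ang_i, ang_j, ang_k, ang_ka, ang_t0,
            anc_i, anc_site, anc_k,
            wall_i, wall_sign, wall_z, wall_k) -> np.ndarray:
    f = np.zeros_like(x)
    # bonds: E = 1/2 k (r - r0)^2
    if len(bond_i):
        d = x[bond_j] - x[bond_i]
        r = np.linalg.norm(d, axis=1)
        r = np.maximum(r, 1e-12)
        mag = (bond_k * (r - bond_r0) / r)[:, None] * d
        np.add.at(f, bond_i, mag)
        np.add.at(f, bond_j, -mag)
    # angles: E = 1/2 k (theta - theta0)^2, vertex at j
    if len(ang_i):
        u = x[ang_i] - x[ang_j]
        v = x[ang_k] - x[ang_j]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        cos_t = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
        theta = np.arccos(cos_t)
        sin_t = np.maximum(np.sqrt(1.0 - cos_t ** 2), 1e-8)
        dE = ang_ka * (theta - ang_t0)
        gi = (cos_t[:, None] * uh - vh) / (nu * sin_t)[:, None]
        gk = (cos_t[:, None] * vh - uh) / (nv * sin_t)[:, None]
        np.add.at(f, ang_i, -dE[:, None] * gi)
        np.add.at(f, ang_k, -dE[:, None] * gk)
        np.add.at(f, ang_j, dE[:, None] * (gi + gk))
    # anchors
    if len(anc_i):
        f[anc_i] -= anc_k[:, None] * (x[anc_i] - anc_site)
    # half-harmonic walls: sign +1 keeps z >= bound, -1 keeps z <= bound
    if len(wall_i):
        z = x[wall_i, 2]
        viol = wall_sign * (wall_z - z)  # > 0 when on the wrong side
        push = np.where(viol > 0, wall_k * viol * wall_sign, 0.0)
        np.add.at(f[:, 2], wall_i, push)
    return f


def simulate(topo: BeadTopology, config: SimulationConfig) -> Trajectory:
    """Overdamped Langevin (Euler–Maruyama) sampling of the bead model.

    x ← x + (dt/γ)·F(x) + sqrt(2·kT·dt/γ)·η with standard-normal η per
    coordinate; the PRNG is seeded from ``config.seed`` so identical
    seed + config reproduces the trajectory exactly. Frames are written
    every ``stride`` steps (including the initial configuration) as one CA
    pseudo-atom per bead, with a static membrane lattice appended when
    configured.
    """
    rng = np.random.default_rng(config.seed)
    x = topo.rest_positions.copy()
    n = topo.n_beads
    bond_i = np.array([b[0] for b in topo.bonds], dtype=int)
    bond_j = np.array([b[1] for b in topo.bonds], dtype=int)
    bond_k = np.array([b[2] for b in topo.bonds])
    bond_r0 = np.array([b[3] for b in topo.bonds])
    ang_i = np.array([a[0] for a in topo.angles], dtype=int)
    ang_j = np.array([a[1] for a in topo.angles], dtype=int)
    ang_k = np.array([a[2] for a in topo.angles], dtype=int)
    ang_ka = np.array([a[3] for a in topo.angles])
    ang_t0 = np.array([a[4] for a in topo.angles])
    anc_i = np.array([a[0] for a in topo.anchors], dtype=int)
    anc_site = np.array([a[1] for a in topo.anchors]) if topo.anchors else np.zeros((0, 3))
    anc_k = np.array([a[2] for a in topo.anchors])
    wall_i = np.array([w[0] for w in topo.walls], dtype=int)
    wall_sign = np.array([w[1] for w in topo.walls])
    wall_z = np.array([w[2] for w in topo.walls])
    wall_k = np.array([w[3] for w in topo.walls])

    dt = config.dt
    gamma = config.friction
    noise_scale = math.sqrt(2.0 * config.kT * dt / gamma)
    max_step = 10.0  # Å; larger deterministic moves flag instability

    frames = [x.copy()]
    chunk = 2000
    step = 0
    while step < config.n_steps:
        todo = min(chunk, config.n_steps - step)
        eta = rng.standard_normal((todo, n, 3))
        for s in range(todo):
            f = _forces(x, bond_i, bond_j, bond_k, bond_r0,
                        ang_i, ang_j, ang_k, ang_ka, ang_t0,
                        anc_i, anc_site, anc_k,
                        wall_i, wall_sign, wall_z, wall_k)
            drift = (dt / gamma) * f
            if np.max(np.abs(drift)) > max_step:
                raise NumericalError(
                    f"integration unstable at step {step + s}: "
                    f"|F|*dt/gamma = {np.max(np.abs(drift)):.1f} Å > {max_step} Å")
            x = x + drift + noise_scale * eta[s]
            if (step + s + 1) % config.stride == 0:
                frames.append(x.copy())
        step += todo

    bead_coords = np.stack(frames)
    topology = [
        AtomRecord(serial=i + 1, name="CA", element="C", residue_name="BEA",
                   residue_id=i + 1, chain_id="A",
                   position=topo.rest_positions[i].copy(), is_hetero=False)
        for i in range(n)
    ]
    coords = bead_coords
    if config.include_membrane:
        mem = _membrane_lattice(config.membrane_nx, config.membrane_ny,
                                config.membrane_spacing, config.slab_halfwidth)
        for k, (xy_z) in enumerate(mem):
            topology.append(AtomRecord(
                serial=n + k + 1, name="P", element="P", residue_name="POP",
                residue_id=1000 + k, chain_id="M", position=xy_z.copy(),
                is_hetero=True))
        mem_block = np.broadcast_to(mem, (coords.shape[0],) + mem.shape)
        coords = np.concatenate([coords, mem_block], axis=1)
    return Trajectory(topology, coords)


def _membrane_lattice(nx: int, ny: int, spacing: float, halfwidth: float,
                      interior_planes: int = 0) -> np.ndarray:
    xs = (np.arange(nx) - (nx - 1) / 2.0) * spacing
    ys = (np.arange(ny) - (ny - 1) / 2.0) * spacing
    zs = [halfwidth, -halfwidth]
    if interior_planes:
        zs += list(np.linspace(-halfwidth, halfwidth, interior_planes + 2)[1:-1])
    pts = [[x, y, z] for z in zs for y in ys for x in xs]
    return np.asarray(pts)


def domain_map_for(topo: BeadTopology, config: SimulationConfig) -> DomainMap:
    """Domain map matching the emitted pseudo-atom trajectory.

    Bead residue ids are sequential in chain order; the single SI blob bead
    stands in for the polybasic/ITAM groups so the contact and burial stages
    run on synthetic input unmodified.
    """
    domains: dict[str, list[tuple[str, int, int]]] = {}
    for i, role in enumerate(topo.roles):
        rid = i + 1
        if role not in domains:
            domains[role] = [("A", rid, rid)]
        else:
            chain, lo, hi = domains[role][0]
            domains[role] = [(chain, min(lo, rid), max(hi, rid))]
    si_rid = topo.roles.index("SI") + 1
    groups = {"PBR1": [si_rid], "ITAM1": [si_rid], "ITAM_TYR": [si_rid]}
    return DomainMap(domains=domains, groups=groups, membrane_residue="POP",
                     membrane_slab_halfwidth=config.slab_halfwidth)


# ---------------------------------------------------------------------------
# Deterministic fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request; see :func:`make_fixture`."""

    kind: str  # helix | strand | rigid_copies | membrane_slab
    params: dict = field(default_factory=dict)
    seed: int | None = None


# canonical backbone geometry (Å, degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_OMEGA = 180.0


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension placement: |c−d| = bond, ∠(b,c,d) = angle,
    torsion(a,b,c,d) = torsion."""
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    u = c - b
    u /= np.linalg.norm(u)
    ab = b - a
    n = np.cross(ab, u)
    n /= np.linalg.norm(n)
    m = np.cross(n, u)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        -bond * math.sin(theta) * math.sin(phi),
    ])
    return c + d_local[0] * u + d_local[1] * m + d_local[2] * n


def _build_backbone(n_res: int, phi: float, psi: float) -> Frame:
    if n_res < 3:
        raise ConfigError("backbone fixtures need at least 3 residues")
    coords: list[np.ndarray] = []
    # residue 1 seeded in the x-y plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    th = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(th), math.sin(th), 0.0])
    coords += [n0, ca0, c0]
    for _ in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[-3], coords[-2], coords[-1]
        n_new = _place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi)
        ca_new = _place_atom(ca_prev, c_prev, n_new, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_new = _place_atom(c_prev, n_new, ca_new, _B_CA_C, _A_N_CA_C, phi)
        coords += [n_new, ca_new, c_new]
    topo = []
    serial = 1
    for res in range(n_res):
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C")):
            topo.append(AtomRecord(serial=serial, name=name, element=element,
                                   residue_name="ALA", residue_id=res + 1,
                                   chain_id="A",
                                   position=coords[serial - 1].copy()))
            serial += 1
    return Frame(topo, np.asarray(coords))


def make_helix(n_res: int = 12, phi: float = -57.0, psi: float = -47.0) -> Frame:
    """Ideal α-helical backbone built at exactly the requested (φ, ψ)."""
    return _build_backbone(n_res, phi, psi)


def make_strand(n_res: int = 8, phi: float = -139.0, psi: float = 135.0) -> Frame:
    """Ideal extended-strand backbone at exactly the requested (φ, ψ)."""
    return _build_backbone(n_res, phi, psi)


def make_rigid_copies(base: Frame, n_copies: int, rotation_deg: float = 0.0,
                      axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
                      translation: tuple[float, float, float] = (0.0, 0.0, 0.0),
                      noise_sigma: float = 0.0, seed: int = 0) -> Trajectory:
    """Trajectory of rigid-motion copies of a base frame.

    Copy k is the base rotated by k·rotation_deg about ``axis`` and
    translated by k·translation, with optional i.i.d. Gaussian noise of
    width ``noise_sigma`` (seeded).
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    axis_v = np.asarray(axis, dtype=float)
    axis_v /= np.linalg.norm(axis_v)
    frames = []
    for k in range(n_copies):
        rot = Rotation.from_rotvec(np.radians(rotation_deg * k) * axis_v)
        coords = rot.apply(base.coords) + np.asarray(translation) * k
        if noise_sigma > 0:
            coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
        frames.append(coords)
    return Trajectory(base.topology, np.stack(frames))


def make_membrane_slab(nx: int = 10, ny: int = 10, spacing: float = 8.0,
                       halfwidth: float = 15.0, interior_planes: int = 0) -> Frame:
    """HETATM pseudo-lipid lattice at z = ±halfwidth (plus interior planes)."""
    pts = _membrane_lattice(nx, ny, spacing, halfwidth, interior_planes)
    topo = [AtomRecord(serial=i + 1, name="P", element="P", residue_name="POP",
                       residue_id=1000 + i, chain_id="M", position=p.copy(),
                       is_hetero=True)
            for i, p in enumerate(pts)]
    return Frame(topo, pts)


def make_fixture(spec: FixtureSpec) -> Frame | Trajectory:
    """Dispatch a :class:`FixtureSpec` to its builder."""
    p = dict(spec.params)
    if spec.kind == "helix":
        return make_helix(**p)
    if spec.kind == "strand":
        return make_strand(**p)
    if spec.kind == "rigid_copies":
        if spec.seed is not None:
            p.setdefault("seed", spec.seed)
        return make_rigid_copies(**p)
    if spec.kind == "membrane_slab":
        return make_membrane_slab(**p)
    raise ConfigError(f"unknown fixture kind '{spec.kind}'")
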