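"""Candidate-structure generation.

Two samplers produce the structure pools that ensemble reweighting consumes:

* :func:`dock_rigid` — a Cartesian rigid-body Metropolis simulated-annealing
  docker that places the mobile partner against the receptor segment by
  minimizing a PRE restraint energy plus soft-sphere repulsion (with an
  exclusion term keeping the ligand off the spin-label conformers).  It
  stands in for a torsion-angle-dynamics docking protocol with the same
  restraint physics.
* :func:`randomize_linker` — torsion-space randomization of a short flexible
  backbone stretch; everything downstream of the linker (the receptor's
  C-terminal helix together with the docked partner) moves as one rigid body
  relative to the fixed core, and clashing conformations are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .forward import LabeledStructure, PREModelParams, _site_gamma2
from .geometry import (
    apply_transform,
    build_backbone,
    frame_from_points,
    random_rotation,
    rotation_about_axis,
    transform_between_frames,
)

__all__ = [
    "RigidBody",
    "LinkerSpec",
    "PoolConfig",
    "LinkedAssembly",
    "DockSchedule",
    "DockPose",
    "clash_filter",
    "randomize_linker",
    "dock_rigid",
]


@dataclass
class RigidBody:
    """A rigid group of atoms, optionally carrying spin-label sites or probes.

    ``sites`` maps site_id → conformer centers (copies, conformers, 3);
    ``probe_ids``/``probe_xyz`` list methyl probes riding on the body.
    """

    atoms: np.ndarray
    sites: dict[str, np.ndarray] = field(default_factory=dict)
    probe_ids: list[str] = field(default_factory=list)
    probe_xyz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.ndim != 2 or self.atoms.shape[1] != 3 or len(self.atoms) == 0:
            raise ValueError("atoms must be a nonempty (n, 3) array")
        if not np.all(np.isfinite(self.atoms)):
            raise ValueError("non-finite atom coordinates")
        if self.probe_xyz is not None:
            self.probe_xyz = np.asarray(self.probe_xyz, dtype=float)


@dataclass(frozen=True)
class LinkerSpec:
    """Flexible backbone stretch to randomize.

    ``residue_range`` is the inclusive residue interval; every residue in the
    range contributes a (φ, ψ) torsion pair.  A degenerate range with
    ``hi == lo - 1`` freezes all torsions (pool members are copies of the
    base pose).
    """

    residue_range: tuple[int, int] = (352, 357)

    def __post_init__(self) -> None:
        lo, hi = self.residue_range
        if hi < lo - 1:
            raise ValueError("invalid residue range")

    @property
    def n_residues(self) -> int:
        return self.residue_range[1] - self.residue_range[0] + 1


@dataclass(frozen=True)
class PoolConfig:
    """Pool-generation settings.

    ``clash_cutoff`` is the inter-body heavy-atom distance (Å) below which a
    conformation is rejected; ``membrane_z`` optionally rejects conformations
    placing mobile atoms above a half-space boundary (off by default — pools
    may contain membrane-facing orientations, filtered at interpretation
    time).
    """

    n_target: int = 1000
    clash_cutoff: float = 2.5
    seed: int = 0
    max_attempts_factor: int = 200
    membrane_z: float | None = None

    def __post_init__(self) -> None:
        if self.n_target < 0:
            raise ValueError("n_target must be >= 0")
        if not self.clash_cutoff > 0:
            raise ValueError("clash_cutoff must be positive")


@dataclass
class LinkedAssembly:
    """Base geometry for linker randomization.

    The fixed body (receptor core plus any non-engaged subunit parts) never
    moves.  The mobile unit (C-terminal helix plus the docked partner with
    its probes, and any label sites riding on the helix) is rebuilt rigidly
    from the backbone frame at the end of the linker.
    """

    fixed_atoms: np.ndarray
    anchor: np.ndarray                       # (3,3) N,CA,C before the linker
    base_phi_psi: np.ndarray                 # (n_linker, 2) radians
    mobile_atoms: np.ndarray                 # heavy atoms of the mobile unit
    probe_ids: list[str]
    probe_xyz: np.ndarray                    # probes at the base pose
    mobile_sites: dict[str, np.ndarray]      # sites riding on the mobile unit
    fixed_sites: dict[str, np.ndarray]       # sites on the fixed body

    def __post_init__(self) -> None:
        self.fixed_atoms = np.asarray(self.fixed_atoms, dtype=float)
        self.mobile_atoms = np.asarray(self.mobile_atoms, dtype=float)
        self.probe_xyz = np.asarray(self.probe_xyz, dtype=float)
        self.anchor = np.asarray(self.anchor, dtype=float)
        self.base_phi_psi = np.atleast_2d(np.asarray(self.base_phi_psi, dtype=float))

    def base_frame(self):
        bb = build_backbone(self.anchor, self.base_phi_psi)
        return frame_from_points(*bb[-1])

    def all_sites(self) -> dict[str, np.ndarray]:
        out = {k: v.copy() for k, v in self.fixed_sites.items()}
        for k, v in self.mobile_sites.items():
            out[k] = np.concatenate([out[k], v], axis=0) if k in out else v.copy()
        return out


def clash_filter(
    body_a: np.ndarray, body_b: np.ndarray, cutoff: float = 2.5
) -> bool:
    """True (keep) iff no atom of ``body_a`` is within ``cutoff`` Å of ``body_b``."""
    a = np.asarray(body_a, dtype=float)
    b = np.asarray(body_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        return True
    tree = cKDTree(a)
    d, _ = tree.query(b, k=1, distance_upper_bound=cutoff)
    return bool(np.all(np.isinf(d)))


def _member_from_transform(
    assembly: LinkedAssembly, R: np.ndarray, t: np.ndarray, meta: dict
) -> LabeledStructure:
    sites = {k: v.copy() for k, v in assembly.fixed_sites.items()}
    for k, v in assembly.mobile_sites.items():
        moved = apply_transform(v.reshape(-1, 3), R, t).reshape(v.shape)
        sites[k] = np.concatenate([sites[k], moved], axis=0) if k in sites else moved
    return LabeledStructure(
        probe_ids=list(assembly.probe_ids),
        probe_xyz=apply_transform(assembly.probe_xyz, R, t),
        sites=sites,
        atoms=apply_transform(assembly.mobile_atoms, R, t),
        meta=meta,
    )


def randomize_linker(
    assembly: LinkedAssembly,
    spec: LinkerSpec,
    cfg: PoolConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[LabeledStructure], dict]:
    """Draw clash-free pool members by randomizing the linker torsions.

    φ/ψ pairs of every linker residue are drawn uniformly in (−180°, 180°];
    the backbone is rebuilt by forward kinematics and the mobile unit is
    carried rigidly by the frame of the last linker residue.  Members whose
    mobile unit clashes with the fixed body (or crosses the optional membrane
    half-space) are rejected.  Returns the stored members plus a stats dict
    (attempts, acceptance fraction).

    With an empty torsion spec (``n_residues`` linker torsions all frozen via
    ``spec.residue_range`` degenerating) the pool is identical copies of the
    base pose.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    if spec.n_residues > len(assembly.base_phi_psi):
        raise ValueError("linker spec longer than the assembly's linker")
    base_frame = assembly.base_frame()
    tree = cKDTree(assembly.fixed_atoms)

    members: list[LabeledStructure] = []
    attempts = 0
    cap = max(cfg.max_attempts_factor * max(cfg.n_target, 1), 1000)
    while len(members) < cfg.n_target:
        if attempts >= cap:
            rate = len(members) / attempts
            if rate < 1e-3:
                raise RuntimeError(
                    f"linker randomization acceptance {rate:.2e} below 0.1%: "
                    "review the assembly geometry / clash cutoff"
                )
            cap *= 2
        attempts += 1
        phi_psi = assembly.base_phi_psi.copy()
        phi_psi[: spec.n_residues] = rng.uniform(
            -np.pi, np.pi, size=(spec.n_residues, 2)
        )
        bb = build_backbone(assembly.anchor, phi_psi)
        frame = frame_from_points(*bb[-1])
        R, t = transform_between_frames(base_frame, frame)
        mobile = apply_transform(assembly.mobile_atoms, R, t)
        if cfg.membrane_z is not None and np.any(mobile[:, 2] > cfg.membrane_z):
            continue
        d, _ = tree.query(mobile, k=1, distance_upper_bound=cfg.clash_cutoff)
        if not np.all(np.isinf(d)):
            continue
        members.append(
            _member_from_transform(
                assembly,
                R,
                t,
                meta={
                    "member": len(members),
                    "torsions_deg": np.rad2deg(phi_psi).round(3).tolist(),
                    "transform_R": R,
                    "transform_t": t,
                },
            )
        )
    stats = {
        "attempts": attempts,
        "accepted": len(members),
        "acceptance": len(members) / attempts if attempts else 1.0,
    }
    return members, stats


# ---------------------------------------------------------------------------
# rigid-body docking


@dataclass(frozen=True)
class DockSchedule:
    """Simulated-annealing schedule for rigid-body docking.

    Geometric cooling from ``t_start`` to ``t_end`` over ``n_steps`` Metropolis
    moves; move amplitudes (translation σ in Å, rotation σ in radians) shrink
    with the same geometric factor from their ``*_start`` values to
    ``*_end``.
    """

    t_start: float = 200.0
    t_end: float = 0.05
    n_steps: int = 600
    trans_start: float = 2.0
    trans_end: float = 0.15
    rot_start: float = 0.25
    rot_end: float = 0.015
    w_pre: float = 1.0
    w_rep: float = 10.0
    rep_radius: float = 3.0
    w_label: float = 10.0
    label_radius: float = 5.0
    greedy_steps: int = 50
    polish_maxfev: int = 800
    #: candidate starts screened per annealing run (best one is optimized)
    n_trial_starts: int = 192


@dataclass
class DockPose:
    R: np.ndarray
    t: np.ndarray
    energy: float
    e_pre: float
    e_rep: float
    run: int

    def apply(self, points: np.ndarray) -> np.ndarray:
        return apply_transform(points, self.R, self.t)


def _dock_energy(
    R, t, receptor_tree, receptor_sites, ligand, obs_vec, obs_index, params, sched
):
    probes = apply_transform(ligand.probe_xyz, R, t)
    calc = np.concatenate(
        [_site_gamma2(probes, receptor_sites[sid], params) for sid in obs_index]
    )
    e_pre = sched.w_pre * float(np.sum((obs_vec - calc) ** 2))
    atoms = apply_transform(ligand.atoms, R, t)
    d, _ = receptor_tree.query(atoms, k=1, distance_upper_bound=sched.rep_radius)
    overlap = sched.rep_radius - d[np.isfinite(d)]
    e_rep = sched.w_rep * float(np.sum(overlap**2))
    # keep the ligand off the spin-label conformers (the labels need space)
    e_lab = 0.0
    for sid in obs_index:
        centers = receptor_sites[sid].reshape(-1, 3)
        dd = np.linalg.norm(atoms[None, :, :] - centers[:, None, :], axis=-1)
        ov = sched.label_radius - dd[dd < sched.label_radius]
        e_lab += sched.w_label * float(np.sum(ov**2))
    return e_pre + e_rep + e_lab, e_pre, e_rep


def dock_rigid(
    receptor: RigidBody,
    ligand: RigidBody,
    observed: dict[str, np.ndarray],
    params: PREModelParams | None = None,
    schedule: DockSchedule | None = None,
    n_runs: int = 50,
    seed: int = 0,
) -> list[DockPose]:
    """PRE-restrained rigid-body docking by Metropolis simulated annealing.

    ``observed`` maps receptor site_id → per-probe Γ₂ vector ordered like
    ``ligand.probe_ids``.  The energy is
    ``w_pre·Σ_i (Γ₂ᵒᵇˢ(i) − Γ₂ᶜᵃˡᶜ(i))² + soft-sphere repulsion`` plus a
    label-exclusion penalty.  ``n_runs`` independent annealing runs are
    started from random poses derived from ``seed``; poses are returned
    sorted by energy (rank 1 = the selected lowest-energy structure).
    Deterministic given ``seed``.
    """
    if not observed:
        raise ValueError("empty PRE restraint set")
    n_restraints = sum(np.count_nonzero(np.isfinite(v)) for v in observed.values())
    if n_restraints < 3:
        raise ValueError("need observed Γ₂ for at least 3 probes")
    if ligand.probe_xyz is None or not ligand.probe_ids:
        raise ValueError("ligand carries no methyl probes")
    params = params or PREModelParams()
    sched = schedule or DockSchedule()

    obs_index = sorted(observed)
    for sid in obs_index:
        if sid not in receptor.sites:
            raise KeyError(f"receptor has no spin-label site {sid!r}")
    obs_vec = np.concatenate([np.asarray(observed[s], float) for s in obs_index])
    receptor_tree = cKDTree(receptor.atoms)

    # start poses exploit the strongest restraint: the probe with the largest
    # observed Γ₂ must sit at that PRE's implied distance from its label
    # site, with the ligand oriented so this probe faces the site; runs
    # differ by the approach direction, the spin about it, and a random tilt
    gmax, anchor_site = max(
        (float(np.max(observed[s])), s) for s in obs_index
    )
    # one candidate anchor per subunit copy of the strongest site (the data
    # cannot say which symmetric copy causes the PRE; runs cycle over them)
    anchor_copies = receptor.sites[anchor_site].mean(axis=1)
    j_star = int(np.argmax(np.asarray(observed[anchor_site], float)))
    r_star = (params.K / max(gmax, 1e-3)) ** (1.0 / 6.0)
    lig_centroid = ligand.probe_xyz.mean(axis=0)
    u_star = ligand.probe_xyz[j_star] - lig_centroid
    u_norm = float(np.linalg.norm(u_star))
    u_star = u_star / u_norm if u_norm > 1e-9 else np.array([1.0, 0.0, 0.0])

    cool = (sched.t_end / sched.t_start) ** (1.0 / max(sched.n_steps - 1, 1))
    amp_cool_t = (sched.trans_end / sched.trans_start) ** (
        1.0 / max(sched.n_steps - 1, 1)
    )
    amp_cool_r = (sched.rot_end / sched.rot_start) ** (1.0 / max(sched.n_steps - 1, 1))

    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    poses: list[DockPose] = []
    energy_args = (receptor_tree, receptor.sites, ligand, obs_vec, obs_index, params, sched)
    for run, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        # screen many informed starts (site copy × approach direction × spin
        # about the approach axis) and anneal from the lowest-energy one
        best_start = None
        for _ in range(max(sched.n_trial_starts, 1)):
            anchor_xyz = anchor_copies[rng.integers(len(anchor_copies))]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            R0 = _align_rotation(u_star, -direction)
            R0 = rotation_about_axis(direction, rng.uniform(-np.pi, np.pi)) @ R0
            t0 = (anchor_xyz + direction * r_star) - ligand.probe_xyz[j_star] @ R0.T
            e0 = _dock_energy(R0, t0, *energy_args)[0]
            if best_start is None or e0 < best_start[0]:
                best_start = (e0, R0, t0)
        R, t = best_start[1], best_start[2]

        def _powell(R0, t0):
            center0 = lig_centroid @ R0.T + t0

            def pose(x):
                R_loc = _rotvec_matrix(x[:3]) @ R0
                return R_loc, center0 + x[3:] - lig_centroid @ R_loc.T

            res = minimize(
                lambda x: _dock_energy(*pose(x), *energy_args)[0],
                np.zeros(6), method="Powell",
                options={"maxfev": sched.polish_maxfev, "xtol": 1e-6, "ftol": 1e-10},
            )
            R1, t1 = pose(res.x)
            return (_dock_energy(R1, t1, *energy_args), R1, t1)

        # polish the informed start before annealing (annealing at full
        # temperature would otherwise immediately scramble it)
        (e, e_pre, e_rep), R, t = _powell(R, t)
        best = (e, R, t, e_pre, e_rep)

        T, s_t, s_r = sched.t_start, sched.trans_start, sched.rot_start
        for _ in range(sched.n_steps):
            R_new, t_new = _propose(rng, R, t, s_t, s_r, lig_centroid)
            e_new, ep_new, er_new = _dock_energy(R_new, t_new, *energy_args)
            if e_new <= e or rng.random() < math.exp(-(e_new - e) / T):
                R, t, e = R_new, t_new, e_new
                if e < best[0]:
                    best = (e, R, t, ep_new, er_new)
            T *= cool
            s_t *= amp_cool_t
            s_r *= amp_cool_r
        # greedy polish: small downhill-only moves from the best-so-far pose
        e, R, t = best[0], best[1], best[2]
        for _ in range(sched.greedy_steps):
            R_new, t_new = _propose(rng, R, t, sched.trans_end, sched.rot_end, lig_centroid)
            e_new, ep_new, er_new = _dock_energy(R_new, t_new, *energy_args)
            if e_new < e:
                R, t, e = R_new, t_new, e_new
                best = (e, R, t, ep_new, er_new)
        # deterministic local refinement of the 6-DOF pose (the r⁻⁶ restraint
        # surface is steep near the optimum; stochastic moves stall early)
        (e_fin, ep_fin, er_fin), R_fin, t_fin = _powell(best[1], best[2])
        if np.isfinite(e_fin) and e_fin < best[0]:
            best = (e_fin, R_fin, t_fin, ep_fin, er_fin)
        poses.append(DockPose(best[1], best[2], best[0], best[3], best[4], run))
    poses.sort(key=lambda p: (p.energy, p.run))
    return poses


def _align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation taking unit vector ``a`` onto unit vector ``b``."""
    v = np.cross(a, b)
    s = float(np.linalg.norm(v))
    c = float(np.dot(a, b))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate π about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        return rotation_about_axis(axis, np.pi)
    return rotation_about_axis(v / s, math.atan2(s, c))


def _rotvec_matrix(v: np.ndarray) -> np.ndarray:
    """Rotation matrix from a rotation vector (axis · angle); identity at 0."""
    angle = float(np.linalg.norm(v))
    if angle < 1e-12:
        return np.eye(3)
    return rotation_about_axis(v / angle, angle)


def _propose(rng, R, t, s_t, s_r, lig_centroid):
    """Perturb the pose: random-axis rotation about the current ligand centroid
    plus a Gaussian translation."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    dR = rotation_about_axis(axis, rng.normal(0.0, s_r))
    center = lig_centroid @ R.T + t
    R_new = dR @ R
    t_new = center - lig_centroid @ R_new.T + rng.normal(0.0, s_t, size=3)
    return R_new, t_new
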