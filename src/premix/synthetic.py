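"""Synthetic toy complexes with planted ground-truth ensembles.

The generator emulates the geometry of a four-fold symmetric channel
(receptor) whose cytoplasmic core carries two spin-label sites per subunit,
plus a C-terminal helix per subunit carrying a third site.  One subunit's
helix is connected to the core through a flexible six-residue backbone
linker and carries a rigidly docked binding partner (ligand) studded with
methyl probes.  Randomizing the linker torsions swings the helix–ligand unit
around the fixed core, which is exactly the degree of freedom the ensemble
reweighting is asked to recover.

A hidden "true" ensemble of a few linker conformations with known population
weights generates the observed PREs; noisy paramagnetic/diamagnetic
intensity tables are produced through the forward intensity-ratio equation,
so the full analysis chain (inversion, back-calculation, weight fitting) can
be validated against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .forward import LabeledStructure, PREModelParams, backcalc_pool
from .geometry import apply_transform, build_backbone, frame_from_points
from .peaks import HMQCSettings, MethylPeakRecord, eq1_forward
from .pool import LinkedAssembly, LinkerSpec, PoolConfig, randomize_linker

__all__ = [
    "ToyConfig",
    "ToySystem",
    "NoiseModel",
    "DockToy",
    "make_toy_system",
    "make_dock_toy",
    "simulate_observed",
    "make_pool_with_truth",
]

# exact four-fold rotation about z
_R90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])

#: default effective correlation time of the toy complex (s); short enough
#: that measurable PREs arise from sharp near-field (8–15 Å) contacts
TOY_TAU_C = 4e-9

#: label-site names, mimicking the cysteine attachment points of the study
SITE_CORE_A = "Q344C"
SITE_CORE_B = "V351C"
SITE_HELIX = "L366C"

# deterministic conformer offsets (Å) representing the flexible label linker
_CONF_OFFSETS = 3.2 * np.array(
    [
        [1.0, 0.0, 0.3],
        [0.3, 0.9, -0.4],
        [-0.2, -0.8, 0.6],
        [0.8, -0.5, -0.5],
        [0.1, 0.4, 1.0],
    ]
)


@dataclass(frozen=True)
class ToyConfig:
    """Geometry and truth-ensemble settings of the toy complex.

    Defaults give 60 methyl probes, 3 label sites × 4 symmetric copies, and a
    5-member true ensemble with populations spanning 0.05–0.30.

    Each planted member k must leave an informative, measurable PRE
    signature: its peak ensemble contribution w_k·max_i Γ₂ᵏ(i) has to fall in
    ``truth_contrib_range`` (s⁻¹) — strong enough to stand clearly above the
    propagated Γ₂ noise, yet weak enough that the corresponding peaks are not
    broadened beyond detection.  Members are also kept mutually distinct:
    ligand centroids at least ``min_truth_separation`` Å apart and fingerprint
    cosine similarity at most ``truth_cos_max`` (a member whose footprint is
    indistinguishable from another's — or absent — carries no recoverable
    population information).
    """

    n_probes: int = 60
    n_ligand_atoms: int = 140
    ligand_radius: float = 15.0
    probe_radius: float = 13.5
    n_linker_residues: int = 6
    n_true: int = 5
    true_weights: tuple[float, ...] | None = None
    min_truth_separation: float = 15.0
    truth_contrib_range: tuple[float, float] = (20.0, 45.0)
    truth_cos_max: float = 0.5
    clash_cutoff: float = 2.5

    def resolved_weights(self) -> np.ndarray:
        if self.true_weights is not None:
            w = np.asarray(self.true_weights, dtype=float)
            if len(w) != self.n_true or np.any(w < 0):
                raise ValueError("true_weights must be n_true nonnegative values")
            return w
        if self.n_true == 1:
            return np.array([0.30])
        return np.linspace(0.30, 0.05, self.n_true)


@dataclass(frozen=True)
class NoiseModel:
    """Intensity-level noise and diamagnetic-rate draw ranges.

    ``snr_para``/``snr_dia`` are spectral signal-to-noise ratios relative to
    the diamagnetic peak intensity (σ = I_dia / snr); ``math.inf`` disables
    noise.  The diamagnetic rates are drawn once per methyl, uniformly from
    the given ranges (s⁻¹), the magnitudes typical of methyl-TROSY peaks of
    very large complexes.
    """

    snr_para: float = 50.0
    snr_dia: float = 50.0
    r2_diaH_range: tuple[float, float] = (20.0, 50.0)
    r2_diaHC_range: tuple[float, float] = (30.0, 70.0)

    def __post_init__(self) -> None:
        if not (self.snr_para > 0 and self.snr_dia > 0):
            raise ValueError("signal-to-noise ratios must be positive")


@dataclass
class ToySystem:
    """A toy receptor–ligand complex with a planted true ensemble."""

    assembly: LinkedAssembly
    linker_spec: LinkerSpec
    truth_members: list[LabeledStructure]
    truth_weights: np.ndarray
    receptor_atoms: np.ndarray            # fixed body, for overlays / density frame
    config: ToyConfig
    seed: int
    params: PREModelParams = field(default_factory=PREModelParams)

    @property
    def site_ids(self) -> list[str]:
        return sorted(self.assembly.all_sites())

    @property
    def probe_ids(self) -> list[str]:
        return list(self.assembly.probe_ids)

    def pool_config(self, n_target: int, seed: int | None = None) -> PoolConfig:
        return PoolConfig(
            n_target=n_target,
            clash_cutoff=self.config.clash_cutoff,
            seed=self.seed if seed is None else seed,
        )


def _cyl(r: float, theta_deg: float, z: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    return np.array([r * np.cos(t), r * np.sin(t), z])


def _subunit_core() -> np.ndarray:
    """Deterministic atom lattice of one subunit's core (cytoplasmic blob)."""
    pts = []
    for r in (11.0, 14.0):
        for theta in np.arange(-35.0, 36.0, 10.0):
            for z in (-14.0, -10.0, -6.0, -2.0):
                pts.append(_cyl(r, theta, z))
    return np.array(pts)


def _replicate_c4(points: np.ndarray, n: int = 4) -> list[np.ndarray]:
    """Copies of a point set under exact successive 90° rotations about z."""
    out = [np.asarray(points, dtype=float)]
    for _ in range(n - 1):
        out.append(out[-1] @ _R90.T)
    return out


def make_toy_system(
    cfg: ToyConfig | None = None,
    seed: int = 0,
    params: PREModelParams | None = None,
) -> ToySystem:
    """Build the toy complex and draw its clash-free true ensemble.

    Deterministic given ``seed``.  The receptor's label-site copies are
    related by exact four-fold rotations about z; truth poses are drawn from
    the same linker-randomization distribution the decoy pool uses, subject
    to the informativeness constraints of :class:`ToyConfig` (per-member
    contribution window, centroid separation, fingerprint-cosine cap).

    ``params`` defaults to an effective correlation time of 4 ns, placing
    measurable PRE contacts in the 8–15 Å near-field range where footprints
    vary sharply with pose (the regime in which population recovery is
    well-posed); the analysis must back-calculate with the same parameters.
    """
    cfg = cfg or ToyConfig()
    params = params or PREModelParams(tau_c=TOY_TAU_C)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7051]))

    core0 = _subunit_core()
    cores = _replicate_c4(core0)

    # core label sites of subunit 0 (conformers = center + fixed offsets)
    site_a0 = _cyl(16.0, -15.0, -3.0) + _CONF_OFFSETS * np.array([1.0, 1.0, 1.0])
    site_b0 = _cyl(16.0, 15.0, -6.0) + _CONF_OFFSETS * np.array([1.0, -1.0, 1.0])

    # linker anchor backbone (N, CA, C) at the top of subunit 0's core
    anchor0 = np.array(
        [[11.2, -1.4, -1.2], [12.0, 0.0, -0.8], [13.1, 0.7, 0.1]]
    )
    base_phi_psi = np.deg2rad(
        np.tile([-120.0, 130.0], (cfg.n_linker_residues, 1))
    )

    # mobile unit, defined in the local frame of the last linker residue:
    # a 12-residue helical CA trace plus the rigidly docked ligand
    i = np.arange(12)
    helix_local = np.column_stack(
        [
            2.0 + 1.5 * i,
            2.3 * np.cos(np.deg2rad(100.0) * i),
            2.3 * np.sin(np.deg2rad(100.0) * i),
        ]
    )
    site_l_local = helix_local[7] + _CONF_OFFSETS * np.array([0.8, 1.0, 1.0])

    lig_center = np.array([46.0, 20.0, 0.0])
    probes_local = lig_center + _ball(rng, cfg.n_probes, cfg.probe_radius)
    lig_atoms_local = lig_center + _ball(rng, cfg.n_ligand_atoms, cfg.ligand_radius)

    # realize the base pose of subunit 0's mobile unit in world coordinates
    bb0 = build_backbone(anchor0, base_phi_psi)
    R0, o0 = frame_from_points(*bb0[-1])
    helix0 = helix_local @ R0.T + o0
    site_l0 = site_l_local @ R0.T + o0
    probes0 = probes_local @ R0.T + o0
    lig_atoms0 = lig_atoms_local @ R0.T + o0

    # four symmetric copies of everything receptor-side
    helices = _replicate_c4(helix0)
    sites_a = _replicate_c4(site_a0)
    sites_b = _replicate_c4(site_b0)
    sites_l = _replicate_c4(site_l0)

    # fixed body: all four cores + the three non-engaged helices (at base pose)
    fixed_atoms = np.concatenate(cores + helices[1:])
    fixed_sites = {
        SITE_CORE_A: np.stack(sites_a),
        SITE_CORE_B: np.stack(sites_b),
        SITE_HELIX: np.stack(sites_l[1:]),   # copies on the fixed helices
    }
    mobile_sites = {SITE_HELIX: np.stack([site_l0])}  # engaged copy, moves

    probe_ids = [f"M{i + 1:03d}" for i in range(cfg.n_probes)]
    assembly = LinkedAssembly(
        fixed_atoms=fixed_atoms,
        anchor=anchor0,
        base_phi_psi=base_phi_psi,
        mobile_atoms=np.concatenate([helix0, lig_atoms0]),
        probe_ids=probe_ids,
        probe_xyz=probes0,
        mobile_sites=mobile_sites,
        fixed_sites=fixed_sites,
    )
    spec = LinkerSpec((352, 352 + cfg.n_linker_residues - 1))

    # draw the clash-free truth poses: one "slot" per population weight, each
    # requiring the member's peak ensemble contribution w_k·max Γ₂ to fall in
    # the measurable window, plus mutual separation in space and in
    # fingerprint direction
    from .forward import backcalc_structure

    weights = cfg.resolved_weights()
    slots: list[LabeledStructure | None] = [None] * cfg.n_true
    fingerprints: list[np.ndarray | None] = [None] * cfg.n_true
    pool_cfg = PoolConfig(n_target=1, clash_cutoff=cfg.clash_cutoff, seed=seed)
    lo, hi = cfg.truth_contrib_range
    attempts = 0
    while any(s is None for s in slots):
        attempts += 1
        if attempts > 20000 * cfg.n_true:
            raise RuntimeError(
                "could not draw a clash-free, informative, mutually distinct "
                "true ensemble; review the toy geometry / contribution window"
            )
        members, _ = randomize_linker(assembly, spec, pool_cfg, rng)
        cand = members[0]
        f = backcalc_structure(cand, params).to_numpy()
        gmax = float(f.max())
        fn = f / np.linalg.norm(f)
        centroid = cand.probe_xyz.mean(axis=0)
        for k, w in enumerate(weights):
            if slots[k] is not None or not (lo <= w * gmax <= hi):
                continue
            if any(
                s is not None
                and np.linalg.norm(centroid - s.probe_xyz.mean(axis=0))
                < cfg.min_truth_separation
                for s in slots
            ):
                break
            if any(
                fp is not None and float(fn @ fp) > cfg.truth_cos_max
                for fp in fingerprints
            ):
                break
            cand.meta["truth_index"] = k
            slots[k] = cand
            fingerprints[k] = fn
            break

    return ToySystem(
        assembly=assembly,
        linker_spec=spec,
        truth_members=[s for s in slots if s is not None],
        truth_weights=weights,
        receptor_atoms=fixed_atoms,
        config=cfg,
        seed=seed,
        params=params,
    )


def _ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """n points uniform in a ball of the given radius."""
    pts = np.empty((n, 3))
    k = 0
    while k < n:
        cand = rng.uniform(-radius, radius, size=(2 * (n - k), 3))
        keep = cand[np.sum(cand**2, axis=1) <= radius**2]
        take = min(len(keep), n - k)
        pts[k : k + take] = keep[:take]
        k += take
    return pts


def true_gamma2(
    system: ToySystem, params: PREModelParams | None = None
) -> pd.Series:
    """Noise-free ensemble-averaged Γ₂ of the planted truth."""
    params = params or system.params
    calc = backcalc_pool(system.truth_members, params)
    vals = system.truth_weights @ calc.to_numpy()
    return pd.Series(vals, index=calc.columns, name="gamma2_true")


def simulate_observed(
    system: ToySystem,
    params: PREModelParams | None = None,
    settings: HMQCSettings | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> dict[str, list[MethylPeakRecord]]:
    """Generate noisy per-site intensity tables from the planted truth.

    Γ₂ᵗʳᵘᵉ(i) = Σ_k w_k Γ₂ᶜᵃˡᶜ'ᵏ(i) is pushed through the forward
    intensity-ratio equation; Gaussian noise with σ = I_dia/snr is added
    independently to the paramagnetic and diamagnetic intensities (noise
    enters at the intensity level, where it arises experimentally, so the
    nonlinearity of the inversion is exercised).  Diamagnetic rates are drawn
    once per methyl.  Returns site → list of peak records.
    """
    params = params or system.params
    settings = settings or HMQCSettings()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(np.random.SeedSequence([system.seed, seed, 0x51]))

    gtrue = true_gamma2(system, params)
    # per-methyl diamagnetic rates, shared across label sites
    r2h = {
        m: rng.uniform(*noise.r2_diaH_range) for m in system.probe_ids
    }
    r2hc = {
        m: rng.uniform(*noise.r2_diaHC_range) for m in system.probe_ids
    }

    sigma_para = 0.0 if math.isinf(noise.snr_para) else 1.0 / noise.snr_para
    sigma_dia = 0.0 if math.isinf(noise.snr_dia) else 1.0 / noise.snr_dia

    tables: dict[str, list[MethylPeakRecord]] = {}
    for site in system.site_ids:
        records = []
        for m in system.probe_ids:
            g = float(gtrue[(site, m)])
            ratio = eq1_forward(g, r2h[m], r2hc[m], settings)
            i_dia = 1.0 + (rng.normal(0.0, sigma_dia) if sigma_dia else 0.0)
            i_para = ratio + (rng.normal(0.0, sigma_para) if sigma_para else 0.0)
            i_dia = max(i_dia, 1e-6)  # diamagnetic reference peaks are observed
            records.append(
                MethylPeakRecord(
                    methyl_id=m,
                    I_para=i_para,
                    I_dia=i_dia,
                    sigma_para=sigma_para,
                    sigma_dia=sigma_dia,
                    R2_diaH=r2h[m],
                    R2_diaHC=r2hc[m],
                )
            )
        tables[site] = records
    return tables


def make_pool_with_truth(
    system: ToySystem,
    n_decoys: int,
    params: PREModelParams | None = None,
    seed: int = 0,
    fingerprint_floor: float = 0.15,
    fingerprint_cos_max: float = 0.8,
) -> tuple[list[LabeledStructure], np.ndarray, pd.DataFrame]:
    """Truth members plus clash-free decoys, with the Γ₂ matrix.

    Decoys are drawn from the linker-randomization distribution (the same
    sampler the analysis uses, so the fit faces realistic degeneracy), except
    that decoy fingerprints must stay distinguishable from the planted
    members' for population recovery to be a well-posed question: a decoy is
    rejected if its Γ₂ fingerprint lies within ``fingerprint_floor`` relative
    distance of a truth fingerprint (a near-duplicate would only split the
    weight) or points within ``fingerprint_cos_max`` cosine similarity of one
    (a same-direction decoy is an equivalent substitute at a rescaled
    population).  Returns (pool, truth indices, calc matrix); the pool is
    truth-first, reproducible given ``seed``.
    """
    params = params or system.params
    truth_calc = backcalc_pool(system.truth_members, params)
    truth_F = truth_calc.to_numpy()
    truth_norm = np.linalg.norm(truth_F, axis=1)
    truth_N = truth_F / truth_norm[:, None]

    pool = list(system.truth_members)
    rows = [truth_F]
    rng = np.random.default_rng(np.random.SeedSequence([system.seed, seed, 0xD0]))
    n_kept = 0
    batch = max(min(n_decoys, 2000), 1)
    while n_kept < n_decoys:
        want = min(batch, n_decoys - n_kept)
        members, _ = randomize_linker(
            system.assembly,
            system.linker_spec,
            PoolConfig(n_target=want, clash_cutoff=system.config.clash_cutoff, seed=0),
            rng,
        )
        calc = backcalc_pool(members, params)
        F = calc.to_numpy()
        # min relative distance of each decoy fingerprint to any truth fingerprint
        d = np.linalg.norm(F[:, None, :] - truth_F[None, :, :], axis=2)
        rel = (d / truth_norm[None, :]).min(axis=1)
        fnorm = np.maximum(np.linalg.norm(F, axis=1, keepdims=True), 1e-30)
        cos = ((F / fnorm) @ truth_N.T).max(axis=1)
        accept = (rel > fingerprint_floor) & (cos < fingerprint_cos_max)
        for m, row, ok in zip(members, F, accept):
            if ok and n_kept < n_decoys:
                m.meta["member"] = len(pool)
                pool.append(m)
                rows.append(row[None, :])
                n_kept += 1
    matrix = pd.DataFrame(np.concatenate(rows), columns=truth_calc.columns)
    truth_idx = np.arange(len(system.truth_members))
    return pool, truth_idx, matrix


@dataclass
class DockToy:
    """A two-body docking problem with a known true ligand pose.

    The receptor is a single subunit (core lattice plus C-terminal helix)
    carrying one copy of each of the three label sites; the ligand sits at a
    known clash-free standoff pose, and ``observed`` holds the noiseless Γ₂
    restraints back-calculated from that pose.  ``ligand.probe_xyz`` IS the
    true pose, so the docking recovery error is the RMSD between the docked
    and the stored probe coordinates.
    """

    receptor: "RigidBody"
    ligand: "RigidBody"
    observed: dict[str, np.ndarray]
    params: PREModelParams
    seed: int


def make_dock_toy(seed: int = 0, params: PREModelParams | None = None) -> DockToy:
    """Two-body docking toy with smooth long-range PRE restraints.

    Unlike the pool system (sharp near-field contacts), this emulates the
    docking stage of the analysis, where PREs act as 15–35 Å distance
    restraints: the default correlation time is 50 ns, so the restraint
    energy surface is smooth enough for annealing to find the pose basin,
    and three non-collinear single-copy sites triangulate the pose uniquely
    among proper rigid motions.
    """
    from .pool import RigidBody, clash_filter

    params = params or PREModelParams()  # 50 ns default: long-range regime
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD0C]))

    core = _subunit_core()
    i = np.arange(12)
    # helix of the same subunit at an idealized pose above the core
    helix = np.column_stack(
        [
            14.0 + 1.2 * i,
            2.3 * np.cos(np.deg2rad(100.0) * i),
            2.0 + 1.0 * i,
        ]
    )
    sites = {
        SITE_CORE_A: (_cyl(16.0, -15.0, -3.0) + _CONF_OFFSETS)[None],
        SITE_CORE_B: (_cyl(16.0, 15.0, -6.0) + _CONF_OFFSETS * np.array([1.0, -1.0, 1.0]))[None],
        SITE_HELIX: (helix[7] + _CONF_OFFSETS * np.array([0.8, 1.0, 1.0]))[None],
    }
    receptor = RigidBody(atoms=np.concatenate([core, helix]), sites=sites)

    # true ligand pose: a probe ball roughly equidistant from the three
    # sites, so every site contributes strong restraints and the pose is
    # firmly triangulated
    center = np.array([49.0, -1.0, -6.0])
    probe_xyz = center + _ball(rng, 60, 13.5)
    atoms = center + _ball(rng, 140, 15.0)
    ligand = RigidBody(
        atoms=atoms,
        probe_ids=[f"M{k + 1:03d}" for k in range(60)],
        probe_xyz=probe_xyz,
    )
    if not clash_filter(receptor.atoms, atoms, 2.5):
        raise RuntimeError("dock toy construction produced a clashing true pose")

    truth = LabeledStructure(
        probe_ids=list(ligand.probe_ids),
        probe_xyz=probe_xyz,
        sites=sites,
        atoms=atoms,
    )
    from .forward import backcalc_structure

    g = backcalc_structure(truth, params)
    observed = {s: g.xs(s, level="site").to_numpy() for s in sites}
    return DockToy(receptor, ligand, observed, params, seed)
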