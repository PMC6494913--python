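"""Back-calculation of PRE rates from candidate complex structures.

The PRE on a methyl ¹H from a nitroxide spin label is modeled with the
Solomon–Bloembergen point-dipole form with a single effective correlation
time τ_c:

    Γ₂(r) = K · r⁻⁶,
    K = (1/15)(μ₀/4π)² γ_H² g² μ_B² S(S+1) [4τ_c + 3τ_c/(1 + ω_H²τ_c²)]

with γ_H the proton gyromagnetic ratio, g the electron g-factor, μ_B the Bohr
magneton and S = 1/2 for a nitroxide.  Label flexibility is handled by
averaging r⁻⁶ over a small conformer ensemble of paramagnetic-center
positions (⟨r⁻⁶⟩, the static limit appropriate when label motion is slow on
the relaxation timescale), and the contributions of the symmetric subunit
copies carrying the label are summed, relaxation rates being additive over
independent paramagnetic centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PREModelParams",
    "SpinLabelSite",
    "MethylProbe",
    "LabeledStructure",
    "sb_gamma2",
    "backcalc_structure",
    "backcalc_pool",
    "write_gamma2_matrix",
    "read_gamma2_matrix",
]

# physical constants (SI)
_MU0_4PI = 1e-7                    # T m / A
_GAMMA_H = 2.6752218744e8          # rad s^-1 T^-1, proton
_G_ELECTRON = 2.00231930436256
_MU_B = 9.2740100783e-24           # J / T
_M6_TO_A6 = 1e60


@dataclass(frozen=True)
class PREModelParams:
    """Spectral parameters of the point-dipole PRE model.

    Parameters
    ----------
    tau_c : float
        Effective electron-nucleus correlation time in seconds.  Default
        50 ns, the rotational-diffusion order of magnitude of a ~400 kDa
        membrane-protein complex.
    field_mhz : float
        ¹H Larmor frequency in MHz (sets ω_H = 2π·field).  Default 600.
    spin : float
        Electron spin quantum number; 1/2 for a nitroxide radical.
    """

    tau_c: float = 50e-9
    field_mhz: float = 600.0
    spin: float = 0.5

    def __post_init__(self) -> None:
        if not self.tau_c > 0:
            raise ValueError("tau_c must be positive")
        if not self.field_mhz > 0:
            raise ValueError("field_mhz must be positive")

    @property
    def omega_H(self) -> float:
        """¹H Larmor angular frequency, rad/s."""
        return 2.0 * np.pi * self.field_mhz * 1e6

    @property
    def K(self) -> float:
        """Dipolar prefactor in s⁻¹·Å⁶ (Γ₂ = K·r⁻⁶ for r in Å)."""
        S = self.spin
        pref = (
            (1.0 / 15.0)
            * _MU0_4PI**2
            * _GAMMA_H**2
            * _G_ELECTRON**2
            * _MU_B**2
            * S
            * (S + 1.0)
        ) * _M6_TO_A6
        tc = self.tau_c
        spectral = 4.0 * tc + 3.0 * tc / (1.0 + (self.omega_H * tc) ** 2)
        return pref * spectral


@dataclass
class SpinLabelSite:
    """A spin-label attachment site and its conformer positions.

    ``conformers`` holds the paramagnetic-center (N–O midpoint) coordinates
    of the label's conformer ensemble for every symmetric subunit copy:
    shape (n_copies, n_conformers, 3) in Å.  Conformers are equally weighted.
    """

    site_id: str
    conformers: np.ndarray

    def __post_init__(self) -> None:
        self.conformers = np.asarray(self.conformers, dtype=float)
        if self.conformers.ndim == 2:  # single copy
            self.conformers = self.conformers[None]
        if self.conformers.ndim != 3 or self.conformers.shape[-1] != 3:
            raise ValueError(
                f"{self.site_id}: conformers must be (copies, conformers, 3)"
            )
        if self.conformers.shape[1] < 1:
            raise ValueError(f"{self.site_id}: need at least one conformer")
        if not np.all(np.isfinite(self.conformers)):
            raise ValueError(f"{self.site_id}: non-finite conformer coordinates")

    @property
    def n_copies(self) -> int:
        return self.conformers.shape[0]

    @property
    def n_conformers(self) -> int:
        return self.conformers.shape[1]


@dataclass(frozen=True)
class MethylProbe:
    """A methyl probe: id and representative ¹H position (Å).

    The position is the centroid of the three methyl protons when protons are
    present in the model, otherwise the methyl carbon position (the sub-Å
    difference is far below the spread of the label-conformer ensemble).
    """

    methyl_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"{self.methyl_id}: invalid probe position")


@dataclass
class LabeledStructure:
    """One candidate complex member: probes plus per-site label conformers.

    ``sites`` maps site_id → conformer array (copies, conformers, 3);
    ``probe_xyz`` is (n_probes, 3) ordered as ``probe_ids``.  ``atoms`` can
    carry heavy-atom coordinates of the mobile partner for clash checks and
    density maps; ``meta`` is free-form provenance (seed, torsions, ...).
    """

    probe_ids: list[str]
    probe_xyz: np.ndarray
    sites: dict[str, np.ndarray]
    atoms: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probe_xyz = np.asarray(self.probe_xyz, dtype=float)
        if self.probe_xyz.shape != (len(self.probe_ids), 3):
            raise ValueError("probe_xyz must be (n_probes, 3) matching probe_ids")
        self.sites = {
            sid: SpinLabelSite(sid, arr).conformers for sid, arr in self.sites.items()
        }


def sb_gamma2(r, params: PREModelParams):
    """Solomon–Bloembergen Γ₂ = K·r⁻⁶ for a distance r in Å (vectorized)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive (label center on the probe?)")
    out = params.K * r**-6
    return float(out) if out.ndim == 0 else out


def _site_gamma2(
    probe_xyz: np.ndarray, conformers: np.ndarray, params: PREModelParams
) -> np.ndarray:
    """Γ₂ per probe for one site: conformer-average r⁻⁶, summed over copies."""
    # (copies, conf, probes) distances
    diff = conformers[:, :, None, :] - probe_xyz[None, None, :, :]
    r2 = np.einsum("kcpx,kcpx->kcp", diff, diff)
    if np.any(r2 <= 0):
        raise ValueError("a probe coincides with a label conformer center")
    r6inv = r2**-3
    return params.K * r6inv.mean(axis=1).sum(axis=0)


def backcalc_structure(
    structure: LabeledStructure,
    params: PREModelParams | None = None,
    site_ids: list[str] | None = None,
) -> pd.Series:
    """Back-calculate Γ₂ for every (site, probe) of one structure.

    For probe i and label site with subunit copies s and conformer centers
    c(s, j):  Γ₂(i) = Σ_s K · mean_j |x_i − c(s, j)|⁻⁶.

    Returns a Series indexed by a (site, methyl_id) MultiIndex.
    """
    params = params or PREModelParams()
    site_ids = site_ids or sorted(structure.sites)
    values = []
    index = []
    for sid in site_ids:
        if sid not in structure.sites:
            raise KeyError(f"structure has no spin-label site {sid!r}")
        g = _site_gamma2(structure.probe_xyz, structure.sites[sid], params)
        values.append(g)
        index.extend((sid, m) for m in structure.probe_ids)
    return pd.Series(
        np.concatenate(values),
        index=pd.MultiIndex.from_tuples(index, names=["site", "methyl_id"]),
        name="gamma2_calc",
    )


def backcalc_pool(
    pool: list[LabeledStructure],
    params: PREModelParams | None = None,
    site_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Γ₂ matrix for a structure pool: rows = members, columns = (site, methyl).

    All members must expose the same sites and probe ids; row order follows
    the pool order.
    """
    if not pool:
        raise ValueError("empty structure pool")
    params = params or PREModelParams()
    site_ids = site_ids or sorted(pool[0].sites)
    ref_probes = pool[0].probe_ids
    rows = np.empty((len(pool), len(site_ids) * len(ref_probes)))
    for k, st in enumerate(pool):
        if st.probe_ids != ref_probes:
            raise ValueError(f"pool member {k} has mismatched probe ids")
        rows[k] = backcalc_structure(st, params, site_ids).to_numpy()
    columns = pd.MultiIndex.from_tuples(
        [(s, m) for s in site_ids for m in ref_probes], names=["site", "methyl_id"]
    )
    return pd.DataFrame(rows, columns=columns)


def write_gamma2_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a back-calculated Γ₂ matrix as TSV (site/methyl header rows)."""
    matrix.to_csv(path, sep="\t")


def read_gamma2_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
    df.columns.names = ["site", "methyl_id"]
    return df
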