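"""Conversion of methyl-TROSY peak intensities to PRE rates.

The PRE contribution Γ₂ to the transverse relaxation of a ¹³CH₃ methyl group
is measured as differential line broadening between a paramagnetic sample
(nitroxide label oxidized) and the diamagnetic reference (label reduced by
ascorbate).  For an HMQC readout the intensity ratio is

    I_para / I_dia = exp(-Γ₂ t_HMQC) R₂ᵈⁱᵃᴴ R₂ᵈⁱᵃᴴᶜ
                     / ((R₂ᵈⁱᵃᴴ + Γ₂)(R₂ᵈⁱᵃᴴᶜ + Γ₂))

where R₂ᵈⁱᵃᴴ and R₂ᵈⁱᵃᴴᶜ are the ¹H single-quantum and ¹H-¹³C
multiple-quantum transverse relaxation rates of the methyl in the diamagnetic
state, and t_HMQC is the magnetization transfer time.  The ratio is strictly
decreasing in Γ₂, so the observed ratio is inverted by bracketed root
finding.  Uncertainties are propagated by the delta method (re-inversion at
ratio ± σ_ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "MethylPeakRecord",
    "HMQCSettings",
    "Gamma2Entry",
    "Gamma2Set",
    "ShiftDelta",
    "PeakFlag",
    "eq1_forward",
    "invert_eq1",
    "relative_intensity",
    "shift_distance",
    "classify_significant",
    "read_peak_table",
    "gamma2_from_table",
    "write_gamma2_table",
    "read_gamma2_table",
]

#: ¹³C shift-difference scaling for combined methyl chemical-shift distances.
CARBON_SHIFT_SCALE = 5.9


class PeakFlag(str, Enum):
    """Disposition of one methyl's Γ₂ determination."""

    OK = "ok"
    #: apparent I_para/I_dia ≥ 1 (negative PRE from noise); Γ₂ set to 0
    NONPOSITIVE = "nonpositive"
    #: peak broadened beyond detection (ratio ≤ 0 or below the noise floor);
    #: Γ₂ reported as a lower bound at the configured cap
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class HMQCSettings:
    """Acquisition parameters entering the intensity-ratio equation.

    Parameters
    ----------
    t_hmqc : float
        Magnetization transfer time of the HMQC element in seconds
        (default 6.9 ms).
    """

    t_hmqc: float = 0.0069

    def __post_init__(self) -> None:
        if not self.t_hmqc > 0:
            raise ValueError(f"t_hmqc must be positive, got {self.t_hmqc}")


@dataclass(frozen=True)
class MethylPeakRecord:
    """One methyl group's peak intensities and diamagnetic relaxation rates.

    ``I_para``/``I_dia`` are peak heights (arbitrary but common units) in the
    paramagnetic and diamagnetic states; ``sigma_para``/``sigma_dia`` are the
    spectral noise levels of the two spectra; ``R2_diaH`` and ``R2_diaHC`` are
    the diamagnetic ¹H single-quantum and ¹H-¹³C multiple-quantum transverse
    relaxation rates in s⁻¹.
    """

    methyl_id: str
    I_para: float
    I_dia: float
    sigma_para: float = 0.0
    sigma_dia: float = 0.0
    R2_diaH: float = 30.0
    R2_diaHC: float = 40.0

    def __post_init__(self) -> None:
        if not self.I_dia > 0:
            raise ValueError(f"{self.methyl_id}: I_dia must be positive")
        if not (self.R2_diaH > 0 and self.R2_diaHC > 0):
            raise ValueError(f"{self.methyl_id}: diamagnetic rates must be positive")
        if self.sigma_para < 0 or self.sigma_dia < 0:
            raise ValueError(f"{self.methyl_id}: noise estimates must be >= 0")

    @property
    def ratio(self) -> float:
        return self.I_para / self.I_dia

    @property
    def ratio_sigma(self) -> float:
        """First-order (delta-method) uncertainty of I_para/I_dia."""
        return abs(self.ratio) * math.sqrt(
            (self.sigma_para / self.I_para) ** 2 + (self.sigma_dia / self.I_dia) ** 2
        ) if self.I_para != 0 else self.sigma_para / self.I_dia


@dataclass(frozen=True)
class Gamma2Entry:
    methyl_id: str
    gamma2: float
    gamma2_err: float
    flag: PeakFlag = PeakFlag.OK


@dataclass
class Gamma2Set:
    """Per-methyl Γ₂ values for one spin-label site.

    Entries are unique by ``methyl_id`` and keep their input order.
    """

    label_site: str
    entries: list[Gamma2Entry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.methyl_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate methyl ids in {self.label_site}: {dup}")
        for e in self.entries:
            if e.flag is PeakFlag.OK and e.gamma2 < 0:
                raise ValueError(f"{e.methyl_id}: negative Γ₂ with flag=ok")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def methyl_ids(self) -> list[str]:
        return [e.methyl_id for e in self.entries]

    def ok_entries(self) -> list[Gamma2Entry]:
        return [e for e in self.entries if e.flag is PeakFlag.OK]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "methyl_id": [e.methyl_id for e in self.entries],
                "gamma2": [e.gamma2 for e in self.entries],
                "gamma2_err": [e.gamma2_err for e in self.entries],
                "flag": [e.flag.value for e in self.entries],
            }
        )


@dataclass(frozen=True)
class ShiftDelta:
    """Combined methyl ¹H/¹³C chemical-shift distance, in ppm."""

    delta_H: float
    delta_C: float
    delta_combined: float


def eq1_forward(
    gamma2: float | np.ndarray,
    R2_diaH: float,
    R2_diaHC: float,
    settings: HMQCSettings | None = None,
) -> float | np.ndarray:
    """Intensity ratio I_para/I_dia expected for a given Γ₂.

    Strictly decreasing in Γ₂; equals 1 at Γ₂ = 0 and tends to 0 as
    Γ₂ → ∞.  Vectorized over ``gamma2``.
    """
    settings = settings or HMQCSettings()
    if not (R2_diaH > 0 and R2_diaHC > 0):
        raise ValueError("diamagnetic rates must be positive")
    g = np.asarray(gamma2, dtype=float)
    if np.any(g < 0):
        raise ValueError("gamma2 must be nonnegative")
    out = (
        np.exp(-g * settings.t_hmqc)
        * R2_diaH
        * R2_diaHC
        / ((R2_diaH + g) * (R2_diaHC + g))
    )
    return float(out) if np.isscalar(gamma2) else out


def _invert_ratio(
    ratio: float, R2_diaH: float, R2_diaHC: float, settings: HMQCSettings
) -> float:
    """Unique Γ₂ ≥ 0 with eq1_forward(Γ₂) = ratio, for ratio in (0, 1]."""
    if ratio >= 1.0:
        return 0.0
    f = lambda g: eq1_forward(g, R2_diaH, R2_diaHC, settings) - ratio
    hi = 10.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - ratio > 0 guarantees a root
            raise RuntimeError("failed to bracket Γ₂ root")
    return brentq(f, 0.0, hi, rtol=1e-9, maxiter=200)


def invert_eq1(
    record: MethylPeakRecord,
    settings: HMQCSettings | None = None,
    *,
    gamma2_cap: float = 80.0,
    noise_floor: float = 3.0,
) -> Gamma2Entry:
    """Invert the measured intensity ratio of one methyl to Γ₂.

    For ratios in (0, 1) the unique root of the forward equation is found by
    bracketed root finding (relative tolerance 1e-9).  Ratios ≥ 1 (apparent
    negative PRE, i.e. noise) map to Γ₂ = 0 with flag ``nonpositive``.
    Ratios ≤ 0 or paramagnetic intensities below ``noise_floor``·σ_para are
    broadened beyond detection: Γ₂ is reported as a lower bound at
    ``gamma2_cap`` with flag ``unresolved``.

    The uncertainty is propagated by re-inverting at ratio ± σ_ratio.
    """
    settings = settings or HMQCSettings()
    ratio = record.ratio
    if ratio <= 0 or record.I_para < noise_floor * record.sigma_para:
        return Gamma2Entry(record.methyl_id, gamma2_cap, math.inf, PeakFlag.UNRESOLVED)
    if ratio >= 1.0:
        return Gamma2Entry(record.methyl_id, 0.0, 0.0, PeakFlag.NONPOSITIVE)

    g = _invert_ratio(ratio, record.R2_diaH, record.R2_diaHC, settings)
    sig = record.ratio_sigma
    if sig > 0:
        lo_ratio = min(ratio + sig, 1.0)
        hi_ratio = ratio - sig
        g_lo = _invert_ratio(lo_ratio, record.R2_diaH, record.R2_diaHC, settings)
        if hi_ratio > 0:
            g_hi = _invert_ratio(hi_ratio, record.R2_diaH, record.R2_diaHC, settings)
        else:
            g_hi = 2 * g - g_lo  # symmetrize when ratio - σ falls below zero
        err = 0.5 * (g_hi - g_lo)
    else:
        err = 0.0
    return Gamma2Entry(record.methyl_id, g, err, PeakFlag.OK)


def relative_intensity(
    I_with: float,
    I_free: float,
    sigma_with: float = 0.0,
    sigma_free: float = 0.0,
) -> tuple[float, float]:
    """Relative peak intensity I_with/I_free and its propagated error.

    ``I_with`` is the intensity in the presence of the binding partner,
    ``I_free`` in its absence.  The error follows the first-order quotient
    formula from the two spectral noise levels.
    """
    if not I_free > 0:
        raise ValueError("I_free must be positive")
    ratio = I_with / I_free
    if I_with == 0:
        err = sigma_with / I_free
    else:
        err = abs(ratio) * math.sqrt(
            (sigma_with / I_with) ** 2 + (sigma_free / I_free) ** 2
        )
    return ratio, err


#: Relative-intensity level below which a methyl is called significantly broadened.
SIGNIFICANT_INTENSITY_REDUCTION = 0.80


def shift_distance(delta_H: float, delta_C: float) -> ShiftDelta:
    """Combined methyl chemical-shift distance Δδ = [(ΔδH)² + (ΔδC/5.9)²]^½."""
    combined = math.hypot(delta_H, delta_C / CARBON_SHIFT_SCALE)
    return ShiftDelta(delta_H, delta_C, combined)


def classify_significant(
    gset: Gamma2Set, threshold: float = 5.0
) -> tuple[list[str], list[str]]:
    """Methyl ids with significant PRE (Γ₂ strictly greater than ``threshold``).

    Returns ``(significant_ids, unresolved_ids)``: only entries with flag
    ``ok`` are classified against the threshold; broadened-out (unresolved)
    entries are reported separately since their Γ₂ is only a lower bound.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    significant = [
        e.methyl_id
        for e in gset.entries
        if e.flag is PeakFlag.OK and e.gamma2 > threshold
    ]
    unresolved = [e.methyl_id for e in gset.entries if e.flag is PeakFlag.UNRESOLVED]
    return significant, unresolved


# ---------------------------------------------------------------------------
# tabular I/O

PEAK_COLUMNS = [
    "methyl_id",
    "I_para",
    "I_dia",
    "sigma_para",
    "sigma_dia",
    "R2_diaH",
    "R2_diaHC",
]


def read_peak_table(path, label_site: str | None = None) -> list[MethylPeakRecord]:
    """Read a per-site intensity table (TSV/CSV) into peak records."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        MethylPeakRecord(
            methyl_id=str(row.methyl_id),
            I_para=float(row.I_para),
            I_dia=float(row.I_dia),
            sigma_para=float(row.sigma_para),
            sigma_dia=float(row.sigma_dia),
            R2_diaH=float(row.R2_diaH),
            R2_diaHC=float(row.R2_diaHC),
        )
        for row in df.itertuples(index=False)
    ]


def gamma2_from_table(
    records: Iterable[MethylPeakRecord],
    label_site: str,
    settings: HMQCSettings | None = None,
    **invert_kwargs,
) -> Gamma2Set:
    """Convert a full per-site intensity table to a :class:`Gamma2Set`."""
    entries = [invert_eq1(r, settings, **invert_kwargs) for r in records]
    return Gamma2Set(label_site=label_site, entries=entries)


def write_gamma2_table(gset: Gamma2Set, path) -> None:
    gset.to_frame().to_csv(path, sep="\t", index=False)


def read_gamma2_table(path, label_site: str) -> Gamma2Set:
    df = pd.read_csv(path, sep="\t")
    entries = [
        Gamma2Entry(
            str(r.methyl_id), float(r.gamma2), float(r.gamma2_err), PeakFlag(r.flag)
        )
        for r in df.itertuples(index=False)
    ]
    return Gamma2Set(label_site=label_site, entries=entries)
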