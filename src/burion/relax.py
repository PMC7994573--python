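"""NMR spin relaxation: T2 from T1rho/T1 with spin-lock offset correction,
heteronuclear NOE ratios, and Monte Carlo uncertainty propagation.

The transverse relaxation rate is recovered from rotating-frame relaxation via

    1/T2 = R1rho / sin^2(theta) - R1 / tan^2(theta),   tan(theta) = omega1/Omega,

where omega1 is the spin-lock field amplitude and Omega the resonance offset
from the spin-lock carrier (both rad/s; only sin^2 and tan^2 enter, so the sign
of Omega is irrelevant).  On resonance (Omega = 0) theta = pi/2 and T2 = T1rho.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi


class NonPhysicalRelaxation(ValueError):
    """Computed 1/T2 <= 0 for the given record."""


@dataclass
class RelaxationRecord:
    label: str
    T1: float            # s
    T1rho: float         # s
    omega1: float        # spin-lock amplitude, rad/s
    Omega: float         # resonance offset from carrier, rad/s
    T1_err: float = 0.0  # s
    T1rho_err: float = 0.0

    def __post_init__(self) -> None:
        if self.T1 <= 0 or self.T1rho <= 0:
            raise ValueError("T1 and T1rho must be positive")
        if self.omega1 <= 0:
            raise ValueError("spin-lock amplitude omega1 must be positive")
        if self.T1_err < 0 or self.T1rho_err < 0:
            raise ValueError("errors must be non-negative")

    @classmethod
    def from_lab_units(cls, label: str, T1: float, T1rho: float,
                       spinlock_khz: float, offset_hz: float,
                       T1_err: float = 0.0, T1rho_err: float = 0.0) -> "RelaxationRecord":
        """Convenience constructor: field amplitude in kHz, offset in Hz."""
        return cls(label=label, T1=T1, T1rho=T1rho,
                   omega1=TWO_PI * spinlock_khz * 1e3,
                   Omega=TWO_PI * offset_hz,
                   T1_err=T1_err, T1rho_err=T1rho_err)


def _tilt_angle(omega1: float, Omega: float) -> float:
    """Effective spin-lock tilt theta = arctan(omega1/Omega); pi/2 on resonance."""
    if Omega == 0.0:
        return np.pi / 2.0
    return float(np.arctan2(omega1, abs(Omega)))


def _r2(T1: float, T1rho: float, theta: float) -> float:
    sin2 = np.sin(theta) ** 2
    tan2 = np.tan(theta) ** 2
    r2 = (1.0 / T1rho) / sin2
    if np.isfinite(tan2) and tan2 > 0:
        r2 -= (1.0 / T1) / tan2
    return float(r2)


def t2_from_t1rho(rec: RelaxationRecord) -> float:
    """T2 in seconds from the offset-corrected rotating-frame rates.

    Raises :class:`NonPhysicalRelaxation` when the correction yields 1/T2 <= 0
    (requires R1rho >= R1*cos^2(theta) for a physical record).
    """
    theta = _tilt_angle(rec.omega1, rec.Omega)
    if theta < 1e-9:
        raise NonPhysicalRelaxation(
            f"{rec.label}: spin-lock tilt angle is degenerate (omega1 << Omega)")
    r2 = _r2(rec.T1, rec.T1rho, theta)
    if r2 <= 0:
        raise NonPhysicalRelaxation(
            f"{rec.label}: computed 1/T2 = {r2:.4g} 1/s is non-physical")
    return 1.0 / r2


def mc_uncertainty(rec: RelaxationRecord, n_draws: int = 1000,
                   rng_seed: int = 0) -> tuple[float, float, int]:
    """Monte Carlo error on T2: perturb T1 and T1rho with independent Gaussian
    noise of the stated errors, recompute T2, return (T2, sd over draws,
    number of non-physical draws dropped)."""
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    t2 = t2_from_t1rho(rec)
    if rec.T1_err == 0 and rec.T1rho_err == 0:
        return t2, 0.0, 0
    rng = np.random.default_rng(rng_seed)
    theta = _tilt_angle(rec.omega1, rec.Omega)
    t1s = rec.T1 + rng.normal(0.0, rec.T1_err, n_draws) if rec.T1_err > 0 \
        else np.full(n_draws, rec.T1)
    t1rs = rec.T1rho + rng.normal(0.0, rec.T1rho_err, n_draws) if rec.T1rho_err > 0 \
        else np.full(n_draws, rec.T1rho)
    sin2 = np.sin(theta) ** 2
    tan2 = np.tan(theta) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (1.0 / t1rs) / sin2
        if np.isfinite(tan2) and tan2 > 0:
            r2 = r2 - (1.0 / t1s) / tan2
    ok = np.isfinite(r2) & (r2 > 0) & (t1s > 0) & (t1rs > 0)
    n_dropped = int(n_draws - ok.sum())
    if ok.sum() < 2:
        raise NonPhysicalRelaxation(f"{rec.label}: all MC draws non-physical")
    sd = float(np.std(1.0 / r2[ok], ddof=1))
    return t2, sd, n_dropped


@dataclass
class HetNoeRecord:
    I_sat: float
    I_ref: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.I_ref == 0:
            raise ValueError("reference intensity must be non-zero")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def hetnoe_ratio(rec: HetNoeRecord) -> tuple[float, float]:
    """NOE = I_sat/I_ref with the error taken as twice the spectral noise SD,
    propagated to first order through the ratio."""
    noe = rec.I_sat / rec.I_ref
    sigma = 2.0 * rec.noise_sd
    err = abs(noe) * np.hypot(sigma / abs(rec.I_sat) if rec.I_sat != 0 else 0.0,
                              sigma / abs(rec.I_ref))
    if rec.I_sat == 0:
        err = sigma / abs(rec.I_ref)
    return float(noe), float(err)


def process_table(df: pd.DataFrame, spinlock_khz: float = 1.5,
                  n_mc: int = 1000, rng_seed: int = 0) -> pd.DataFrame:
    """Add T2, T2_err and flags to a relaxation table.

    Expects columns: residue, T1, T1_err, T1rho, T1rho_err, offset_hz.
    Non-physical rows are flagged and their T2 withheld (NaN), not imputed.
    """
    out = df.copy()
    t2s, errs, flags = [], [], []
    for i, row in df.iterrows():
        rec = RelaxationRecord.from_lab_units(
            label=str(row["residue"]), T1=row["T1"], T1rho=row["T1rho"],
            spinlock_khz=spinlock_khz, offset_hz=row["offset_hz"],
            T1_err=row.get("T1_err", 0.0), T1rho_err=row.get("T1rho_err", 0.0))
        try:
            t2, sd, _ = mc_uncertainty(rec, n_draws=n_mc,
                                       rng_seed=rng_seed + int(i)) \
                if (rec.T1_err > 0 or rec.T1rho_err > 0) \
                else (t2_from_t1rho(rec), 0.0, 0)
            t2s.append(t2); errs.append(sd); flags.append("")
        except NonPhysicalRelaxation:
            t2s.append(np.nan); errs.append(np.nan); flags.append("non_physical")
    out["T2"] = t2s
    out["T2_err"] = errs
    out["flag"] = flags
    return out
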