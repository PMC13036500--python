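"""Closed-form NMR observables and PRE-derived distance restraints.

Covers the composite amide chemical-shift difference, the rotational
correlation time from the 15N T1/T2 ratio with first-order error
propagation, and the conversion between the transverse PRE rate Γ₂ and the
electron-proton distance,

    r = [ K/Γ₂ · (4 τc + 3 τc / (1 + ωH² τc²)) ]^(1/6),

with K the standard PRE proportionality constant for a nitroxide label
(1.23e-32 cm⁶ s⁻², excluded from error propagation).  Amide peaks broadened
beyond detection are assigned the cap rate (170 s⁻¹ by default), which
corresponds to distances of roughly 12 Å or shorter and yields upper-limit
restraints only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PRE_K_CM6_S2",
    "GAMMA2_CAP_DEFAULT",
    "PRERecord",
    "PRETable",
    "PREDistanceRestraint",
    "chemical_shift_difference",
    "correlation_time",
    "gamma2_to_distance",
    "distance_to_gamma2",
    "gamma2_distance_error",
    "derive_pre_restraints",
    "pre_ratio",
]

#: PRE proportionality constant for a nitroxide spin label, cm^6 s^-2.
PRE_K_CM6_S2 = 1.23e-32

#: Default Γ₂ assigned to amide peaks broadened beyond detection, s^-1.
GAMMA2_CAP_DEFAULT = 170.0

_CM_PER_ANGSTROM = 1e-8


@dataclass
class PRERecord:
    """One residue's PRE measurement: Γ₂ = R2,para - R2,dia in s⁻¹."""

    residue: int
    gamma2: float
    gamma2_err: float = 0.0
    status: str = "observed"  # observed | vanished | unreliable

    def __post_init__(self) -> None:
        if self.status not in ("observed", "vanished", "unreliable"):
            raise ValueError(f"unknown PRE status {self.status!r}")
        if self.gamma2_err < 0:
            raise ValueError("gamma2_err must be non-negative")


@dataclass
class PRETable:
    """Per-residue PRE rates with errors and observed/vanished flags."""

    residues: np.ndarray
    gamma2: np.ndarray
    gamma2_err: np.ndarray
    status: np.ndarray

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.gamma2 = np.asarray(self.gamma2, dtype=float)
        self.gamma2_err = np.asarray(self.gamma2_err, dtype=float)
        self.status = np.asarray(self.status, dtype=object)
        n = self.residues.size
        if not (self.gamma2.size == self.gamma2_err.size == self.status.size == n):
            raise ValueError("PRE table columns have unequal lengths")

    def __len__(self) -> int:
        return int(self.residues.size)

    def records(self) -> list[PRERecord]:
        return [
            PRERecord(int(r), float(g), float(e), str(s))
            for r, g, e, s in zip(self.residues, self.gamma2, self.gamma2_err, self.status)
        ]


@dataclass
class PREDistanceRestraint:
    """Distance restraint between a spin-label centre and an amide proton."""

    site: str
    residue: int
    r: float
    upl: float
    lol: float | None
    kind: str  # two_sided | upper_only

    def __post_init__(self) -> None:
        if self.kind not in ("two_sided", "upper_only"):
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if self.kind == "upper_only":
            self.lol = None
        elif self.lol is None or not (self.lol <= self.r <= self.upl):
            raise ValueError("two-sided restraint requires lol <= r <= upl")


def chemical_shift_difference(delta_hn: float, delta_n: float) -> float:
    """Composite amide shift difference √(δHN² + (δN/6.51)²) in ppm."""
    return float(np.sqrt(delta_hn**2 + (delta_n / 6.51) ** 2))


def correlation_time(
    t1: float,
    t2: float,
    nu_n_hz: float,
    t1_err: float = 0.0,
    t2_err: float = 0.0,
) -> tuple[float, float]:
    """Rotational correlation time from the 15N T1/T2 ratio, in seconds.

    τc = √(6 T1/T2 - 7) / (4π νN).  The uncertainty is propagated to first
    order from the T1 and T2 errors.  Valid only above the rigid-limit bound
    6 T1/T2 >= 7.
    """
    if t1 <= 0 or t2 <= 0:
        raise ValueError("relaxation times must be positive")
    radicand = 6.0 * t1 / t2 - 7.0
    if radicand < 0:
        raise ValueError("ratio below rigid-limit bound: 6*T1/T2 < 7")
    root = np.sqrt(radicand)
    denom = 4.0 * np.pi * nu_n_hz
    tau = root / denom
    if radicand == 0:
        return 0.0, np.inf if (t1_err or t2_err) else 0.0
    dtau_dt1 = (6.0 / t2) / (2.0 * root) / denom
    dtau_dt2 = (-6.0 * t1 / t2**2) / (2.0 * root) / denom
    err = float(np.hypot(dtau_dt1 * t1_err, dtau_dt2 * t2_err))
    return float(tau), err


def _spectral_factor(tau_c: float, omega_h: float) -> float:
    return 4.0 * tau_c + 3.0 * tau_c / (1.0 + omega_h**2 * tau_c**2)


def gamma2_to_distance(
    gamma2, tau_c: float, omega_h: float, k: float = PRE_K_CM6_S2
):
    """Electron-proton distance in Å for a transverse PRE rate Γ₂ in s⁻¹.

    ``omega_h`` is the ¹H Larmor frequency in rad/s (2π·ν_H).
    """
    gamma2 = np.asarray(gamma2, dtype=float)
    if np.any(gamma2 <= 0):
        raise ValueError("gamma2 must be positive")
    r_cm = (k / gamma2 * _spectral_factor(tau_c, omega_h)) ** (1.0 / 6.0)
    out = r_cm / _CM_PER_ANGSTROM
    return float(out) if out.ndim == 0 else out


def distance_to_gamma2(
    r_angstrom, tau_c: float, omega_h: float, k: float = PRE_K_CM6_S2
):
    """Γ₂ in s⁻¹ for an electron-proton distance in Å (inverse of the above)."""
    r_cm = np.asarray(r_angstrom, dtype=float) * _CM_PER_ANGSTROM
    if np.any(r_cm <= 0):
        raise ValueError("distance must be positive")
    out = k / r_cm**6 * _spectral_factor(tau_c, omega_h)
    return float(out) if out.ndim == 0 else out


def gamma2_distance_error(
    gamma2: float,
    gamma2_err: float,
    tau_c: float,
    tau_c_err: float,
    omega_h: float,
    k: float = PRE_K_CM6_S2,
) -> float:
    """First-order propagated distance error σr in Å.

    Uses the analytic gradient of the Γ₂→r conversion with respect to Γ₂ and
    τc; the uncertainty of K is not considered.
    """
    r = gamma2_to_distance(gamma2, tau_c, omega_h, k)
    dr_dgamma = -r / (6.0 * gamma2)
    f = _spectral_factor(tau_c, omega_h)
    x = omega_h**2 * tau_c**2
    dfdtau = 4.0 + 3.0 * (1.0 - x) / (1.0 + x) ** 2
    dr_dtau = r / (6.0 * f) * dfdtau
    return float(np.hypot(dr_dgamma * gamma2_err, dr_dtau * tau_c_err))


def derive_pre_restraints(
    records,
    tau_c: float,
    omega_h: float,
    tau_c_err: float = 0.0,
    cap: float = GAMMA2_CAP_DEFAULT,
    k: float = PRE_K_CM6_S2,
    site: str = "",
) -> list[PREDistanceRestraint]:
    """Convert PRE records into distance restraints.

    Observed records give two-sided restraints with upl = r + σr and
    lol = r - σr.  Vanished records (peak broadened beyond detection) give
    upper-limit-only restraints at the cap-equivalent distance.  Records
    whose propagated error exceeds 50% of the distance are dropped as
    unreliable (logged, not raised).  Records with a non-positive rate carry
    no distance information and are skipped.
    """
    if hasattr(records, "records"):
        records = records.records()
    out: list[PREDistanceRestraint] = []
    for rec in records:
        if rec.status == "unreliable":
            continue
        if rec.status == "vanished":
            upl = gamma2_to_distance(cap, tau_c, omega_h, k)
            out.append(
                PREDistanceRestraint(
                    site=site, residue=rec.residue, r=upl, upl=upl, lol=None,
                    kind="upper_only",
                )
            )
            continue
        if rec.gamma2 <= 0:
            logger.debug("residue %d: non-positive PRE rate, no restraint", rec.residue)
            continue
        r = gamma2_to_distance(rec.gamma2, tau_c, omega_h, k)
        sr = gamma2_distance_error(
            rec.gamma2, rec.gamma2_err, tau_c, tau_c_err, omega_h, k
        )
        if sr > 0.5 * r:
            logger.info(
                "residue %d: distance error %.1f%% of %.1f Å exceeds 50%%, dropped",
                rec.residue, 100.0 * sr / r, r,
            )
            continue
        out.append(
            PREDistanceRestraint(
                site=site, residue=rec.residue, r=r,
                upl=r + sr, lol=max(r - sr, 0.0), kind="two_sided",
            )
        )
    return out


def pre_ratio(
    i_para: float, i_dia: float, ref_para: float, ref_dia: float
) -> float:
    """Intensity ratio (I_para/ref_para) / (I_dia/ref_dia)."""
    if ref_para <= 0 or ref_dia <= 0:
        raise ValueError("reference intensities must be positive")
    if i_dia == 0:
        raise ValueError("diamagnetic intensity must be non-zero")
    return float((i_para / ref_para) / (i_dia / ref_dia))
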