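"""Solution biophysics: DLS correlogram fitting, CD units, ESI deconvolution.

The measured DLS intensity autocorrelation g2(tau) is linked to the field
correlation g1(tau) through the Siegert relation

    g2(tau) = B (1 + beta |g1(tau)|^2),

with g1 a sum of exponentials sum_i a_i exp(-Gamma_i tau), a_i >= 0,
sum a_i = 1.  Each decay rate gives a diffusion coefficient D = Gamma / q^2
(q = 4 pi n0 sin(theta/2) / lambda) and a hydrodynamic radius via
Stokes-Einstein, R_h = k_B T / (6 pi eta(T) D).  An empirical globular
protein calibration R_h(nm) = 0.7429 M(kDa)^0.3599 converts radii to
apparent molecular weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Correlogram",
    "DLSFit",
    "DLSComponent",
    "scattering_vector",
    "water_viscosity",
    "fit_correlogram",
    "mw_from_rh",
    "rh_from_mw",
    "mean_residue_ellipticity",
    "CDSpectrum",
    "deconvolve_charge_ladder",
    "size_histogram",
]

K_B = 1.380649e-23  # J/K
PROTON_MASS = 1.00728  # Da

# instrument defaults: He-Ne laser DLS at 90 degrees in aqueous buffer
DEFAULT_WAVELENGTH = 632.8e-9  # m
DEFAULT_ANGLE = 90.0  # degrees
DEFAULT_N0 = 1.331

# R_h(nm) = RH_CAL_A * M(kDa) ** RH_CAL_B for globular proteins
RH_CAL_A = 0.7429
RH_CAL_B = 0.3599


def scattering_vector(n0: float, wavelength_m: float, angle_deg: float) -> float:
    """Scattering vector magnitude q = 4 pi n0 sin(theta/2) / lambda, in 1/m."""
    if not 0.0 < angle_deg <= 180.0:
        raise ValueError("scattering angle must be in (0, 180] degrees")
    return 4.0 * math.pi * n0 * math.sin(math.radians(angle_deg) / 2.0) / wavelength_m


def water_viscosity(temperature_k: float) -> float:
    """Dynamic viscosity of water in Pa s (Vogel-type equation, 273-373 K)."""
    if not 273.0 <= temperature_k <= 373.0:
        raise ValueError("viscosity model valid for 273-373 K")
    # eta = A exp(B / (T - C)); standard VFT constants for water
    return 0.02939e-3 * math.exp(507.88 / (temperature_k - 149.3))


@dataclass
class Correlogram:
    delays: np.ndarray  # s
    g2: np.ndarray
    temperature_k: float = 293.0
    angle_deg: float = DEFAULT_ANGLE
    wavelength_m: float = DEFAULT_WAVELENGTH
    n0: float = DEFAULT_N0

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, float)
        self.g2 = np.asarray(self.g2, float)
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if not np.isfinite(self.g2).all():
            raise ValueError("g2 must be finite")

    @property
    def q(self) -> float:
        return scattering_vector(self.n0, self.wavelength_m, self.angle_deg)


@dataclass
class DLSComponent:
    amplitude: float       # intensity fraction of |g1|
    gamma: float           # decay rate, 1/s
    diffusion: float       # m^2/s
    rh_m: float            # hydrodynamic radius, m

    @property
    def rh_nm(self) -> float:
        return self.rh_m * 1e9


@dataclass
class DLSFit:
    baseline: float  # B
    intercept: float  # beta
    components: list[DLSComponent]
    residual_rms: float
    note: str = ""

    def model(self, delays: np.ndarray) -> np.ndarray:
        g1 = np.zeros_like(np.asarray(delays, float))
        for c in self.components:
            g1 = g1 + c.amplitude * np.exp(-c.gamma * np.asarray(delays, float))
        return self.baseline * (1.0 + self.intercept * g1 ** 2)


class DLSFitError(RuntimeError):
    pass


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def fit_correlogram(c: Correlogram, n_components: int = 2,
                    amplitude_floor: float = 0.01) -> DLSFit:
    """Least-squares Siegert fit with softplus-constrained amplitudes.

    Amplitudes are kept non-negative and normalized to sum to one inside the
    model; decay rates are parameterized on a log scale.  Three fixed
    multi-start initializations spread the rate guesses to avoid local
    minima.  Components whose fitted intensity fraction falls below
    ``amplitude_floor`` trigger a refit with fewer components (noted in the
    result).
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    tau, g2 = c.delays, c.g2
    if len(tau) < 20:
        raise ValueError("need >= 20 delay points")
    b0 = float(np.mean(g2[-max(3, len(g2) // 10):]))
    beta0 = max(g2[0] / b0 - 1.0, 1e-3)
    if g2[0] - b0 <= 0:
        raise DLSFitError("no decay: g2 does not exceed its baseline")
    # crude single-rate guess from the half-decay point
    target = b0 * (1.0 + beta0 * 0.25)
    below = np.nonzero(g2 <= target)[0]
    t_half = tau[below[0]] if len(below) else tau[len(tau) // 2]
    gamma0 = math.log(2.0) / max(t_half, tau[0])

    def unpack(p):
        B, beta = p[0], p[1]
        # clip the log-rate so LM trial steps cannot overflow exp
        gammas = np.exp(np.clip(p[2:2 + n_components], -60.0, 60.0))
        raw = _softplus(np.clip(np.asarray(p[2 + n_components:]), -30.0, 30.0))
        amps = raw / raw.sum()
        return B, beta, gammas, amps

    def residuals(p):
        B, beta, gammas, amps = unpack(p)
        g1 = (amps[None, :] * np.exp(-np.outer(tau, gammas))).sum(axis=1)
        return B * (1.0 + beta * g1 ** 2) - g2

    starts = []
    if n_components == 1:
        starts.append([b0, beta0, math.log(gamma0), 1.0])
    else:
        for split in (3.0, 10.0, 30.0):  # fixed multi-start rate separations
            starts.append([
                b0, beta0,
                math.log(gamma0 * math.sqrt(split)),
                math.log(gamma0 / math.sqrt(split)),
                1.0, 1.0,
            ])
    best = None
    for p0 in starts:
        sol = least_squares(residuals, p0, method="lm", max_nfev=20000)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e-3 * len(tau):
        raise DLSFitError("correlogram fit did not converge")

    B, beta, gammas, amps = unpack(best.x)
    note = ""
    if n_components == 2:
        degenerate = abs(math.log(gammas[0] / gammas[1])) < 0.05
        if amps.min() < amplitude_floor or degenerate:
            sub = fit_correlogram(c, 1)
            sub.note = ("minor/degenerate second component; "
                        "collapsed to 1 component")
            return sub

    q = c.q
    eta = water_viscosity(c.temperature_k)
    comps = []
    order = np.argsort(gammas)[::-1]  # fastest (smallest particle) first
    for i in order:
        D = gammas[i] / q ** 2
        rh = K_B * c.temperature_k / (6.0 * math.pi * eta * D)
        comps.append(DLSComponent(float(amps[i]), float(gammas[i]), D, rh))
    rms = float(np.sqrt(np.mean(residuals(best.x) ** 2)))
    return DLSFit(float(B), float(beta), comps, rms, note)


def round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def rh_from_mw(m_kda: float) -> float:
    """Globular-protein calibration: R_h in nm from mass in kDa."""
    return RH_CAL_A * m_kda ** RH_CAL_B


def mw_from_rh(rh_nm: float, cal_a: float = RH_CAL_A,
               cal_b: float = RH_CAL_B) -> float:
    """Apparent molecular weight (kDa) from hydrodynamic radius (nm).

    Inverts the empirical globular-protein calibration; outside the
    0.5-10 nm globular regime the result is extrapolated (warning).
    """
    if not 0.5 <= rh_nm <= 10.0:
        import logging

        logging.getLogger(__name__).warning(
            "R_h = %.3g nm outside the globular calibration regime", rh_nm
        )
    return (rh_nm / cal_a) ** (1.0 / cal_b)


def size_histogram(fit: DLSFit, n_bins: int = 40,
                   rh_range_nm: tuple[float, float] = (0.5, 1000.0)):
    """Intensity-weighted radius histogram from fit components (log bins)."""
    edges = np.geomspace(rh_range_nm[0], rh_range_nm[1], n_bins + 1)
    weights = np.zeros(n_bins)
    for comp in fit.components:
        i = int(np.clip(np.searchsorted(edges, comp.rh_nm) - 1, 0, n_bins - 1))
        weights[i] += comp.amplitude
    return pd.DataFrame({
        "rh_low_nm": edges[:-1], "rh_high_nm": edges[1:],
        "intensity_fraction": weights,
    })


# ---------------------------------------------------------------------------
# Circular dichroism


@dataclass
class CDSpectrum:
    wavelengths_nm: np.ndarray
    theta_mdeg: np.ndarray
    mw_da: float | None = None
    conc_g_per_ml: float | None = None
    path_cm: float | None = None
    n_residues: int | None = None
    mre: np.ndarray | None = None  # deg cm^2 dmol^-1


def mean_residue_ellipticity(spec: CDSpectrum) -> CDSpectrum:
    """Convert raw ellipticity to mean residue ellipticity, pointwise.

    [theta] = theta * Mw / (N * c * l) with theta in degrees, c in g/ml and
    l in cm yields deg cm^2 mol^-1; division by 10 gives the conventional
    deg cm^2 dmol^-1.
    """
    for name in ("mw_da", "conc_g_per_ml", "path_cm", "n_residues"):
        if getattr(spec, name) in (None, 0):
            raise ValueError(f"CD metadata field {name!r} missing")
    theta_deg = np.asarray(spec.theta_mdeg, float) / 1000.0
    per_mol = theta_deg * spec.mw_da / (
        spec.n_residues * spec.conc_g_per_ml * spec.path_cm
    )
    spec.mre = per_mol / 10.0
    return spec


# ---------------------------------------------------------------------------
# Electrospray charge-ladder deconvolution


class LadderError(ValueError):
    pass


def mass_from_peak(mz: float, z: int, proton_mass: float = PROTON_MASS) -> float:
    """Neutral mass from a single peak with known charge: M = z (m/z - m_p)."""
    return z * (mz - proton_mass)


def deconvolve_charge_ladder(
    peaks: Sequence[tuple[float, float]] | np.ndarray,
    proton_mass: float = PROTON_MASS,
) -> tuple[float, float]:
    """Neutral mass from a ladder of multiply protonated ESI peaks.

    For adjacent peaks m1 > m2 assumed to carry charges z and z + 1,
    z = round((m2 - m_p) / (m1 - m2)); each peak then yields
    M = z (m/z - m_p).  Returns mean +/- sd over the peaks.  Charge
    estimates that do not form one consistent ladder raise ``LadderError``.
    """
    arr = np.asarray(
        [p[0] if isinstance(p, (tuple, list, np.ndarray)) else float(p)
         for p in peaks], float)
    if len(arr) < 2:
        raise LadderError("need >= 2 peaks")
    mz = np.sort(arr)[::-1]  # descending: charge increases down the ladder
    z_first: list[int] = []
    for m1, m2 in zip(mz, mz[1:]):
        if m1 - m2 <= 0:
            raise LadderError("duplicate m/z values")
        z_first.append(int(round((m2 - proton_mass) / (m1 - m2))))
    # pair k relates peaks k (charge z_k) and k+1 (charge z_k + 1)
    for k in range(len(z_first) - 1):
        if z_first[k + 1] != z_first[k] + 1:
            raise LadderError(
                f"inconsistent ladder: adjacent pairs imply charges "
                f"{z_first[k]} and {z_first[k + 1]} for peak {k + 1}"
            )
    charges = [z_first[0] + i for i in range(len(mz))]
    masses = np.array([z * (m - proton_mass) for z, m in zip(charges, mz)])
    sd = float(masses.std(ddof=1)) if len(masses) > 1 else 0.0
    return float(masses.mean()), sd
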