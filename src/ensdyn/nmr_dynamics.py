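"""Backbone 15N relaxation analysis and chemical shift perturbation mapping.

Relaxation rates come from monoexponential fits of peak-intensity decays,
the heteronuclear NOE from saturated/unsaturated intensity ratios, and the
overall rotational correlation time from the trimmed mean R2/R1 ratio of the
rigid core through the isotropic large-molecule closed form

    tau_c = (1 / (4 pi nu_N)) * sqrt(6 <R2/R1> - 7),

valid when relaxation is dominated by overall tumbling (R2/R1 > 7/6).

Titration analysis combines amide 1H and 15N shift changes as

    dd = sqrt(dd_H^2 + (dd_N / w)^2),   w = 6.51 by default,

and tracks cross-peak intensity ratios with a five-residue sliding mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "RelaxationSeries",
    "RateFit",
    "RelaxationRates",
    "TumblingEstimate",
    "CSPProfile",
    "fit_exponential_rate",
    "het_noe",
    "tau_c_from_r2_r1",
    "csp",
    "hotspot_call",
    "read_relaxation_table",
    "read_peak_list",
]

#: |gamma(15N) / gamma(1H)|; nu_N = this times the proton frequency.
GAMMA_RATIO_15N = 0.101329
NITROGEN_CSP_WEIGHT = 6.51


@dataclass
class RelaxationSeries:
    residue: int
    delays: np.ndarray  # s
    intensities: np.ndarray
    duplicates: np.ndarray | None = None  # second measurement at same delays

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, float)
        self.intensities = np.asarray(self.intensities, float)
        if len(np.unique(self.delays)) < 4:
            raise ValueError("need >= 4 distinct delays")
        if not np.isfinite(self.intensities).all():
            raise ValueError("intensities must be finite")


@dataclass
class RateFit:
    residue: int
    rate: float  # s^-1
    err: float
    i0: float
    ok: bool


def fit_exponential_rate(series: RelaxationSeries) -> RateFit:
    """Nonlinear least-squares fit of I(t) = I0 exp(-R t).

    The error is the covariance standard error; when duplicate measurements
    are present their scatter provides the per-point noise estimate.  A
    non-positive or vanishing fitted rate flags the residue for exclusion.
    """
    t, y = series.delays, series.intensities
    sigma = None
    if series.duplicates is not None:
        dup = np.asarray(series.duplicates, float)
        resid = np.abs(y - dup) / 2.0
        s = float(np.sqrt(np.mean(resid ** 2)))
        if s > 0:
            sigma = np.full_like(y, s)
        y = (y + dup) / 2.0
    # log-linear start values (guard non-positive intensities)
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = (math.exp(intercept), max(-slope, 1e-3 / t.max()))
    else:
        p0 = (max(y.max(), 1.0), 1.0 / t.max())
    try:
        popt, pcov = curve_fit(
            lambda tt, i0, r: i0 * np.exp(-r * tt), t, y, p0=p0,
            sigma=sigma, absolute_sigma=sigma is not None, maxfev=5000,
        )
    except RuntimeError:
        return RateFit(series.residue, math.nan, math.nan, math.nan, ok=False)
    i0, rate = popt
    err = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else math.nan
    ok = rate > 0 and rate * t.max() > 1e-6
    return RateFit(series.residue, float(rate), err, float(i0), ok=ok)


def het_noe(
    i_on: float,
    i_off: float,
    duplicates: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Steady-state heteronuclear NOE = I_on / I_off.

    ``duplicates`` are the two ratios from a duplicate experiment pair; the
    reported value is their mean and the error half their absolute
    difference.  Without duplicates the error is NaN.
    """
    if abs(i_off) < 1e-12 * max(abs(i_on), 1.0):
        raise ValueError("I_off is (near) zero")
    if duplicates is not None:
        a, b = duplicates
        return (a + b) / 2.0, abs(a - b) / 2.0
    return i_on / i_off, math.nan


@dataclass
class RelaxationRates:
    residue: int
    r1: float
    r1_err: float
    r2: float
    r2_err: float
    noe: float
    noe_err: float

    @property
    def r2_over_r1(self) -> float:
        return self.r2 / self.r1

    @property
    def valid(self) -> bool:
        return (
            np.isfinite(self.r1) and self.r1 > 0
            and np.isfinite(self.r2) and self.r2 > 0
        )


@dataclass
class TumblingEstimate:
    mean_r2_over_r1: float
    nu_n_hz: float
    tau_c_s: float
    residues_used: list[int]

    @property
    def tau_c_ns(self) -> float:
        return self.tau_c_s * 1e9


def _tau_c(mean_ratio: float, nu_n_hz: float) -> float:
    if mean_ratio <= 7.0 / 6.0:
        raise ValueError(
            f"<R2/R1> = {mean_ratio:.4g} <= 7/6; closed form has no real root"
        )
    return math.sqrt(6.0 * mean_ratio - 7.0) / (4.0 * math.pi * nu_n_hz)


def default_selection(
    rates: Sequence[RelaxationRates],
    noe_min: float = 0.65,
    n_sd: float = 1.0,
    trim: float = 0.1,
) -> list[RelaxationRates]:
    """Rigid-core residues: hetNOE >= noe_min, then drop R2/R1 outliers
    beyond ``n_sd`` standard deviations from the trimmed mean (one pass)."""
    from scipy.stats import trim_mean

    sel = [r for r in rates if r.valid and np.isfinite(r.noe) and r.noe >= noe_min]
    if len(sel) < 5:
        raise ValueError("fewer than 5 residues pass the hetNOE filter")
    ratios = np.array([r.r2_over_r1 for r in sel])
    center = trim_mean(ratios, trim)
    sd = ratios.std(ddof=1)
    keep = np.abs(ratios - center) <= n_sd * sd
    return [r for r, k in zip(sel, keep) if k]


def tau_c_from_r2_r1(
    rates: Sequence[RelaxationRates],
    spectrometer_mhz: float,
    selection: Callable[[Sequence[RelaxationRates]], Sequence[RelaxationRates]]
    | None = None,
) -> TumblingEstimate:
    """Apparent rotational correlation time from the core-average R2/R1.

    ``spectrometer_mhz`` is the proton frequency; the 15N Larmor frequency is
    derived through the gyromagnetic ratio magnitude 0.101329.
    """
    sel = (selection or default_selection)(rates)
    if len(sel) < 5:
        raise ValueError("need >= 5 selected residues")
    mean_ratio = float(np.mean([r.r2_over_r1 for r in sel]))
    nu_n = GAMMA_RATIO_15N * spectrometer_mhz * 1e6
    return TumblingEstimate(
        mean_r2_over_r1=mean_ratio,
        nu_n_hz=nu_n,
        tau_c_s=_tau_c(mean_ratio, nu_n),
        residues_used=[r.residue for r in sel],
    )


# ---------------------------------------------------------------------------
# Titration / CSP


@dataclass
class CSPProfile:
    residues: np.ndarray
    dd_h: np.ndarray       # ppm
    dd_n: np.ndarray       # ppm
    dd_combined: np.ndarray
    intensity_ratio: np.ndarray
    window_ratio: np.ndarray
    nitrogen_weight: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residues,
                "dd_h_ppm": self.dd_h,
                "dd_n_ppm": self.dd_n,
                "dd_combined_ppm": self.dd_combined,
                "intensity_ratio": self.intensity_ratio,
                "window_ratio": self.window_ratio,
            }
        ).set_index("residue")


def sliding_mean(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered sliding mean ignoring NaN; edge windows truncated."""
    half = window // 2
    out = np.full_like(values, np.nan, dtype=float)
    for i in range(len(values)):
        chunk = values[max(0, i - half): i + half + 1]
        good = chunk[np.isfinite(chunk)]
        if len(good):
            out[i] = good.mean()
    return out


def csp(
    free: pd.DataFrame,
    bound: pd.DataFrame,
    nitrogen_weight: float = NITROGEN_CSP_WEIGHT,
    window: int = 5,
) -> CSPProfile:
    """Chemical shift perturbations between a free and a bound spectrum.

    Both inputs are peak tables with columns ``residue``, ``h_ppm``,
    ``n_ppm``, ``intensity``.  Residues present in only one spectrum get NaN
    (missing, never zero) for every derived quantity.
    """
    f = free.set_index("residue") if "residue" in free.columns else free
    b = bound.set_index("residue") if "residue" in bound.columns else bound
    residues = np.array(sorted(set(f.index) | set(b.index)))
    n = len(residues)
    dd_h = np.full(n, np.nan)
    dd_n = np.full(n, np.nan)
    ratio = np.full(n, np.nan)
    for i, res in enumerate(residues):
        if res in f.index and res in b.index:
            dd_h[i] = abs(b.loc[res, "h_ppm"] - f.loc[res, "h_ppm"])
            dd_n[i] = abs(b.loc[res, "n_ppm"] - f.loc[res, "n_ppm"])
            if f.loc[res, "intensity"] != 0:
                ratio[i] = b.loc[res, "intensity"] / f.loc[res, "intensity"]
    dd = np.sqrt(dd_h ** 2 + (dd_n / nitrogen_weight) ** 2)
    return CSPProfile(
        residues=residues,
        dd_h=dd_h,
        dd_n=dd_n,
        dd_combined=dd,
        intensity_ratio=ratio,
        window_ratio=sliding_mean(ratio, window),
        nitrogen_weight=nitrogen_weight,
    )


def hotspot_call(
    profile: CSPProfile,
    k: float = 1.0,
    metric: str = "csp",
) -> set[int]:
    """Residues perturbed above mean + k*sd.

    ``metric`` is ``"csp"`` (combined shift change) or ``"intensity"``
    (windowed intensity *drop*, 1 - window ratio).
    """
    if metric == "csp":
        values = profile.dd_combined
    elif metric == "intensity":
        values = 1.0 - profile.window_ratio
    else:
        raise ValueError(f"unknown metric {metric!r}")
    good = np.isfinite(values)
    if not good.any():
        raise ValueError("profile has no valid values")
    thresh = values[good].mean() + k * values[good].std(ddof=0)
    return set(int(r) for r, v in zip(profile.residues, values)
               if np.isfinite(v) and v > thresh)


# ---------------------------------------------------------------------------
# File formats


def read_relaxation_table(path: str) -> list[RelaxationSeries]:
    """CSV with columns residue, delay_s, intensity[, replicate]."""
    df = pd.read_csv(path, comment="#")
    out = []
    for res, grp in df.groupby("residue"):
        if "replicate" in grp.columns and grp["replicate"].nunique() > 1:
            g1 = grp[grp["replicate"] == grp["replicate"].min()]
            g2 = grp[grp["replicate"] == grp["replicate"].max()]
            g1 = g1.sort_values("delay_s")
            g2 = g2.sort_values("delay_s")
            out.append(RelaxationSeries(
                int(res), g1["delay_s"].to_numpy(),
                g1["intensity"].to_numpy(), g2["intensity"].to_numpy(),
            ))
        else:
            grp = grp.sort_values("delay_s")
            out.append(RelaxationSeries(
                int(res), grp["delay_s"].to_numpy(), grp["intensity"].to_numpy()
            ))
    return out


def read_peak_list(path: str) -> pd.DataFrame:
    """CSV peak list: residue, h_ppm, n_ppm, intensity (extra columns kept)."""
    df = pd.read_csv(path, comment="#")
    required = {"residue", "h_ppm", "n_ppm", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak list {path} lacks columns {sorted(missing)}")
    return df
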