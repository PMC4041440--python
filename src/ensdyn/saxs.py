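"""SAXS: Guinier analysis, Debye bead curves, chi fits, minimal ensembles.

Guinier analysis fits ln I = ln I0 - q^2 Rg^2 / 3 over the low-angle window
q Rg <= 1.3 (determined iteratively).  Theoretical curves from coordinates
use the Debye formula on a one-bead-per-residue (CA) representation with a
uniform form factor:

    I(q) = f^2 sum_i sum_j sinc(q r_ij),  I(0) = (n f)^2.

Experimental/theoretical agreement is measured by the reduced discrepancy

    chi = sqrt( (1/N) sum ((I_exp - c I_theo) / sigma)^2 )

with the scale c fitted analytically.  The minimal ensemble search
exhaustively evaluates all weighted sub-ensembles of up to five candidate
curves and returns the smallest subset whose chi is within a tolerance
factor of the global best.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .structure_io import MonomerModel

__all__ = [
    "ScatteringCurve",
    "GuinierFit",
    "EnsembleSelection",
    "read_dat",
    "write_dat",
    "guinier",
    "debye_curve",
    "chi_fit",
    "minimal_ensemble_search",
]

GUINIER_QRG_MAX = 1.3


@dataclass
class ScatteringCurve:
    q: np.ndarray      # 1/A
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, float)
        self.intensity = np.asarray(self.intensity, float)
        if np.any(np.diff(self.q) <= 0) or np.any(self.q < 0):
            raise ValueError("q must be non-negative and strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, float)
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive")


def read_dat(path: str) -> ScatteringCurve:
    """3-column whitespace/CSV scatter file: q, I, sigma (sigma optional)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", ";")):
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append([float(x) for x in parts[:3]])
            except ValueError:
                continue  # header line
    arr = np.asarray(rows)
    sigma = arr[:, 2] if arr.shape[1] > 2 else None
    if sigma is not None and np.all(sigma == 0.0):
        sigma = None  # placeholder column for an error-free curve
    return ScatteringCurve(arr[:, 0], arr[:, 1], sigma)


def write_dat(curve: ScatteringCurve, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# q(1/A)  I(a.u.)  sigma\n")
        sig = curve.sigma if curve.sigma is not None else np.zeros_like(curve.q)
        for q, i, s in zip(curve.q, curve.intensity, sig):
            fh.write(f"{q:.6g} {i:.6g} {s:.6g}\n")


@dataclass
class GuinierFit:
    rg: float       # A
    i0: float
    q_min: float
    q_max: float
    qrg_max: float
    n_points: int
    mw_kda: float | None = None


class GuinierError(ValueError):
    pass


def guinier(
    curve: ScatteringCurve,
    qrg_max: float = GUINIER_QRG_MAX,
    i0_per_kda: float | None = None,
    max_iter: int = 20,
) -> GuinierFit:
    """Iteratively windowed Guinier fit of the low-angle regime.

    The window starts at the lowest measured q and extends while
    q Rg <= ``qrg_max``; the fit is repeated until Rg changes by < 0.5%.
    ``i0_per_kda`` optionally converts I(0) to a molecular weight.
    """
    q, I = curve.q, curve.intensity
    pos = I > 0
    q, I = q[pos], I[pos]
    sig = curve.sigma[pos] if curve.sigma is not None else None
    if len(q) < 5:
        raise GuinierError("too few positive-intensity points")

    def fit(n: int) -> tuple[float, float]:
        x, y = q[:n] ** 2, np.log(I[:n])
        w = None
        if sig is not None:
            w = (I[:n] / sig[:n]) ** 2  # ln-space weights
        slope, intercept = np.polyfit(x, y, 1, w=w)
        if slope >= 0:
            raise GuinierError("no Guinier regime: non-negative slope")
        return math.sqrt(-3.0 * slope), math.exp(intercept)

    n = min(len(q), max(5, len(q) // 4))
    rg, i0 = fit(n)
    for _ in range(max_iter):
        n_new = int(np.searchsorted(q, qrg_max / rg, side="right"))
        n_new = max(5, min(n_new, len(q)))
        rg_new, i0 = fit(n_new)
        if abs(rg_new - rg) < 0.005 * rg and n_new == n:
            rg = rg_new
            n = n_new
            break
        rg, n = rg_new, n_new
    mw = i0 / i0_per_kda if i0_per_kda else None
    return GuinierFit(rg=rg, i0=i0, q_min=float(q[0]), q_max=float(q[n - 1]),
                      qrg_max=float(q[n - 1] * rg), n_points=n, mw_kda=mw)


def debye_curve(
    models: MonomerModel | Sequence[MonomerModel],
    q: np.ndarray,
    form_factor: float = 1.0,
    bead_atom: str = "CA",
) -> ScatteringCurve:
    """Debye-formula curve from a one-bead-per-residue representation."""
    if isinstance(models, MonomerModel):
        models = [models]
    beads = []
    for m in models:
        for r in m.residues:
            a = r.atom(bead_atom)
            if a is not None:
                beads.append([a.x, a.y, a.z])
    xyz = np.asarray(beads, float)
    if len(xyz) == 0:
        raise ValueError(f"no {bead_atom} beads found")
    q = np.asarray(q, float)
    d = np.sqrt(((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=2))
    dist = d[np.triu_indices(len(xyz), k=1)]
    n = len(xyz)
    I = np.empty_like(q)
    for k, qk in enumerate(q):
        # sinc(0) = 1 handled by numpy's normalized sinc: sinc(x/pi)
        I[k] = n + 2.0 * np.sinc(qk * dist / math.pi).sum()
    return ScatteringCurve(q, form_factor ** 2 * I)


def chi_fit(exp: ScatteringCurve, theo: ScatteringCurve) -> tuple[float, float]:
    """Optimal scale c and discrepancy chi between experiment and theory.

    The theoretical curve is interpolated onto the experimental grid;
    experimental points outside the theoretical q range raise an error.
    """
    if exp.q[0] < theo.q[0] - 1e-12 or exp.q[-1] > theo.q[-1] + 1e-12:
        raise ValueError("experimental q range exceeds theoretical curve")
    it = np.interp(exp.q, theo.q, theo.intensity)
    sigma = exp.sigma if exp.sigma is not None else np.ones_like(exp.q)
    w = 1.0 / sigma ** 2
    c = float((w * exp.intensity * it).sum() / (w * it * it).sum())
    chi2 = float((w * (exp.intensity - c * it) ** 2).sum() / len(exp.q))
    return c, math.sqrt(chi2)


@dataclass
class EnsembleSelection:
    model_ids: list
    weights: np.ndarray
    chi: float
    scale: float


def _weighted_chi(exp: ScatteringCurve, curves: list[np.ndarray]):
    """Non-negative mixture fit of sigma-weighted intensities."""
    sigma = exp.sigma if exp.sigma is not None else np.ones_like(exp.q)
    A = np.stack(curves, axis=1) / sigma[:, None]
    b = exp.intensity / sigma
    coef, _ = nnls(A, b)
    resid = A @ coef - b
    chi = math.sqrt(float((resid ** 2).sum()) / len(b))
    total = coef.sum()
    if total <= 0:
        return np.zeros_like(coef), 0.0, math.inf
    return coef / total, float(total), chi


def minimal_ensemble_search(
    exp: ScatteringCurve,
    pool: Sequence[ScatteringCurve],
    pool_ids: Sequence | None = None,
    max_size: int = 5,
    tolerance: float = 1.05,
) -> EnsembleSelection:
    """Smallest weighted sub-ensemble explaining the experimental curve.

    All subsets of 1..``max_size`` candidate curves are evaluated with
    non-negative normalized weights and a fitted global scale; the smallest
    subset whose chi is within ``tolerance`` of the global best wins.
    """
    if not pool:
        raise ValueError("empty candidate pool")
    if len(pool) > 40:
        raise ValueError("pool too large for exhaustive enumeration (<= 40)")
    ids = list(pool_ids) if pool_ids is not None else list(range(len(pool)))
    interp = [np.interp(exp.q, c.q, c.intensity) for c in pool]

    best_by_size: dict[int, tuple[float, tuple, np.ndarray, float]] = {}
    for size in range(1, min(max_size, len(pool)) + 1):
        for combo in itertools.combinations(range(len(pool)), size):
            w, scale, chi = _weighted_chi(exp, [interp[i] for i in combo])
            cur = best_by_size.get(size)
            if cur is None or chi < cur[0]:
                best_by_size[size] = (chi, combo, w, scale)
    global_best = min(v[0] for v in best_by_size.values())
    for size in sorted(best_by_size):
        chi, combo, w, scale = best_by_size[size]
        if chi <= tolerance * global_best + 1e-12:
            keep = w > 1e-9
            return EnsembleSelection(
                model_ids=[ids[i] for i, k in zip(combo, keep) if k],
                weights=w[keep] / w[keep].sum(),
                chi=chi,
                scale=scale,
            )
    raise AssertionError("unreachable")
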