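"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of the study system: a
two-chain beta-barrel-like dimer toxin with three mobile loops (S1-S2
residues 12-18, S3-S4 residues 48-54, S4-S5 residues 64-70), a 13-residue
purification tag at seq_num <= 0, monoexponential 15N relaxation decays on
standard delay grids, fast-exchange titration shift/intensity patterns with
a localized binding site, Siegert-relation DLS correlograms for mono- and
bi-disperse samples, and Debye-model scatter curves with Gaussian noise.

All randomness flows from a single integer seed through numpy's PCG64
generator (``np.random.default_rng([seed, stream])`` with a fixed stream id
per generator), so outputs are bit-reproducible across platforms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import solution_biophys as sb
from .saxs import ScatteringCurve, debye_curve, write_dat
from .structure_io import (
    Atom,
    CrystalForm,
    MonomerModel,
    ResidueRecord,
    StructureEnsemble,
)

__all__ = [
    "SyntheticSpec",
    "make_ensemble",
    "make_toy_crystal",
    "make_relaxation",
    "make_titration",
    "make_correlogram",
    "make_saxs",
    "write_fixture_suite",
    "TAG_SEQUENCE",
]

#: Purification tag preceding the mature chain; occupies seq_num -12..0.
TAG_SEQUENCE = "GSSHHHHHHSQDP"

#: Default mobile loops (author numbering) and their displacement sigmas (A).
DEFAULT_LOOPS = ((12, 18), (48, 54), (64, 70))

# relaxation delay grids, in seconds
R1_DELAYS = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.9, 1.2, 1.5])
R2_DELAYS = np.array([0.010, 0.030, 0.050, 0.070, 0.090, 0.110, 0.130,
                      0.150, 0.170, 0.210])


@dataclass
class SyntheticSpec:
    """Ground-truth parameters of the synthetic study system."""

    seed: int = 0
    n_models: int = 10
    chain_length: int = 114
    mobile_loops: tuple = tuple((iv, 2.0) for iv in DEFAULT_LOOPS)
    core_sigma: float = 0.2
    # relaxation truth (rigid-core values; loops get scaled values below)
    r1_core: float = 0.9          # 1/s
    r2_core: float = 21.4         # 1/s
    noe_core: float = 0.82
    r1_loop_factor: float = 1.6
    r2_loop_factor: float = 0.6
    noe_loop: float = 0.45
    relax_noise: float = 0.02     # fractional Gaussian noise on intensities
    # titration truth
    site_residues: tuple = tuple(range(12, 19)) + tuple(range(73, 79)) \
        + tuple(range(99, 107))
    max_dd_h: float = 0.12        # ppm at saturation
    max_dd_n: float = 0.65        # ppm at saturation
    saturation_1to1: float = 0.5  # bound fraction at the 1:1 point
    site_intensity_ratio: float = 0.45
    background_intensity_ratio: float = 0.85
    shift_noise: float = 0.003    # ppm
    # DLS truth: list of (R_h nm, intensity fraction)
    dls_components: tuple = ((2.6, 1.0),)
    dls_baseline: float = 1.0
    dls_beta: float = 0.9
    dls_noise: float = 0.01
    temperature_k: float = 293.0
    # SAXS truth
    saxs_rg: float = 23.09        # A
    saxs_i0: float = 7.0
    saxs_noise: float = 0.005
    saxs_mixture: tuple = (0.5, 0.3, 0.2)
    saxs_pool: int = 10

    def loop_set(self) -> set[int]:
        out: set[int] = set()
        for (a, b), _ in self.mobile_loops:
            out.update(range(a, b + 1))
        return out

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2 ** 31), stream])


# ---------------------------------------------------------------------------
# Backbone template


def _template_backbone(n_res: int, radius: float = 9.0,
                       rise: float = 1.5) -> list[ResidueRecord]:
    """Idealized compact backbone: CA trace on a solenoid, N/C/O from the
    local Frenet frame.  Chemically schematic but geometrically protein-like
    (3.8 A CA spacing, finite width, non-collinear)."""
    # arc length per residue ~ 3.8 A
    dtheta = math.sqrt(3.8 ** 2 - rise ** 2) / radius
    idx = np.arange(n_res)
    theta = idx * dtheta
    ca = np.stack([
        radius * np.cos(theta),
        radius * np.sin(theta),
        rise * idx,
    ], axis=1)
    # finite-difference tangents / normals
    tang = np.gradient(ca, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    norm = np.gradient(tang, axis=0)
    nn = np.linalg.norm(norm, axis=1, keepdims=True)
    nn[nn < 1e-9] = 1.0
    norm /= nn
    binorm = np.cross(tang, norm)
    aa_cycle = "ADEFGHIKLMNPQRSTVWY"
    residues = []
    for i in range(n_res):
        c_a = ca[i]
        n_at = c_a - 1.45 * tang[i] + 0.35 * norm[i]
        c_at = c_a + 1.50 * tang[i] + 0.30 * norm[i]
        o_at = c_at + 1.23 * binorm[i]
        residues.append(ResidueRecord(
            seq_num=i + 1,
            aa=aa_cycle[i % len(aa_cycle)],
            atoms=[
                Atom("N", *n_at, 20.0, 1.0),
                Atom("CA", *c_a, 20.0, 1.0),
                Atom("C", *c_at, 20.0, 1.0),
                Atom("O", *o_at, 20.0, 1.0),
            ],
        ))
    return residues


def _sigma_track(spec: SyntheticSpec) -> dict[int, float]:
    track = {i + 1: spec.core_sigma for i in range(spec.chain_length)}
    for (a, b), s in spec.mobile_loops:
        for n in range(a, b + 1):
            if n in track:
                track[n] = s
    return track


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_ensemble(
    spec: SyntheticSpec,
    rigid_transforms: bool = False,
    deletions: dict[int, Sequence[int]] | None = None,
    b_inflate: tuple[tuple[int, int], float] | None = None,
) -> tuple[StructureEnsemble, dict[int, float]]:
    """Ensemble of perturbed copies of the template backbone.

    Every atom of residue *i* in every model is displaced by isotropic
    Gaussian noise with the per-residue sigma (loop or core); optional
    per-model rigid transforms verify superposition invariance; optional
    ``deletions`` remove residues from chosen models to exercise the
    unmodeled-residue placeholder.  Returns the ensemble and the per-residue
    sigma ground truth.
    """
    rng = spec.rng(1)
    rng_rigid = spec.rng(11)  # separate stream: noise identical either way
    template = _template_backbone(spec.chain_length)
    sigma = _sigma_track(spec)
    members = []
    for m in range(spec.n_models):
        drop = set(deletions.get(m, ())) if deletions else set()
        residues = []
        for r in template:
            if r.seq_num in drop:
                continue
            s = sigma[r.seq_num]
            atoms = []
            for a in r.atoms:
                d = rng.normal(0.0, s, size=3) if s > 0 else np.zeros(3)
                b = a.b
                if b_inflate is not None:
                    (lo, hi), extra = b_inflate
                    if lo <= r.seq_num <= hi:
                        b = a.b + extra
                atoms.append(Atom(a.name, a.x + d[0], a.y + d[1], a.z + d[2],
                                  b, a.occ))
            residues.append(ResidueRecord(r.seq_num, r.aa, atoms))
        model = MonomerModel(model_id=str(m + 1), chain_id="A",
                             residues=residues, source="synthetic")
        if rigid_transforms:
            R = _random_rotation(rng_rigid)
            t = rng_rigid.normal(0.0, 20.0, size=3)
            model = model.transformed(R, t, model_id=model.model_id)
        members.append(model)
    return StructureEnsemble(members, label="synthetic"), sigma


# ---------------------------------------------------------------------------
# Toy crystals


def _bumped_chain(spec: SyntheticSpec, loop: tuple[int, int],
                  bump: float) -> MonomerModel:
    """Template chain with ``loop`` residues pushed outward along +x."""
    template = _template_backbone(spec.chain_length)
    lo, hi = loop
    residues = []
    for r in template:
        if lo <= r.seq_num <= hi:
            # flat plateau: every loop residue protrudes by the full bump
            dx = bump
            atoms = [Atom(a.name, a.x + dx, a.y, a.z, a.b, a.occ)
                     for a in r.atoms]
            residues.append(ResidueRecord(r.seq_num, r.aa, atoms))
        else:
            residues.append(r)
    return MonomerModel("1", "A", residues, source="synthetic-crystal")


def make_toy_crystal(
    spec: SyntheticSpec,
    mode: str = "lattice_contact",
    contact_loop: tuple[int, int] = (48, 54),
    gap: float = 4.0,
    cell_a: float | None = None,
) -> tuple[list[MonomerModel], CrystalForm, set[int]]:
    """Chains plus a P1 cell with a designed contact; returns the truth set.

    ``mode``:

    * ``"isolated"`` -- one chain in an oversized cell (no contacts);
    * ``"lattice_contact"`` -- one chain whose ``contact_loop`` protrudes
      toward +x in a cell sized so the +a translate touches it;
    * ``"dimer_contact"`` -- two chains in a huge cell whose contact loops
      face each other ``gap`` A apart (an intra-ASU interface only).
    """
    bump = 10.0
    chain = _bumped_chain(spec, contact_loop, bump)
    _, xyz = chain.atom_coords()
    ext = xyz.max(axis=0) - xyz.min(axis=0)
    margin = 40.0
    if mode == "isolated":
        form = CrystalForm(ext[0] + margin, ext[1] + margin, ext[2] + margin,
                           space_group="P 1", z_asu=1, asu_mass=1.0)
        return [chain], form, set()
    if mode == "lattice_contact":
        if cell_a is None:
            # size a so the +a lattice image approaches to exactly ``gap``
            # (bisection on the true 3D minimum interatomic distance)
            from scipy.spatial import cKDTree

            tree = cKDTree(xyz)

            def min_dist(a: float) -> float:
                d, _ = tree.query(xyz + np.array([a, 0.0, 0.0]), k=1)
                return float(d.min())

            lo, hi = 1.0, ext[0] + 60.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if min_dist(mid) < gap:
                    lo = mid
                else:
                    hi = mid
            cell_a = hi
        form = CrystalForm(cell_a, ext[1] + margin, ext[2] + margin,
                           space_group="P 1", z_asu=1, asu_mass=1.0)
        truth = set(range(contact_loop[0], contact_loop[1] + 1))
        return [chain], form, truth
    if mode == "dimer_contact":
        # partner: chain rotated 180 deg about z so its loop points -x, then
        # placed so the two loop tips face each other across ``gap``
        R = np.diag([-1.0, -1.0, 1.0])  # proper rotation (180 deg about z)
        max_x = xyz[:, 0].max()
        partner = chain.transformed(R, np.zeros(3))
        _, pxyz = partner.atom_coords()
        shift = np.array([max_x + gap - pxyz[:, 0].min(), 0.0, 0.0])
        # re-center partner's y/z onto the chain's loop tip
        tip = xyz[np.argmax(xyz[:, 0])]
        ptip = pxyz[np.argmin(pxyz[:, 0])]
        shift[1] = tip[1] - ptip[1]
        shift[2] = tip[2] - ptip[2]
        partner = partner.transformed(np.eye(3), shift)
        partner = MonomerModel(partner.model_id, "B", partner.residues,
                               partner.source)
        form = CrystalForm(ext[0] * 2 + margin * 3, ext[1] + margin * 2,
                           ext[2] + margin * 2, space_group="P 1",
                           z_asu=1, asu_mass=1.0)
        truth = set(range(contact_loop[0], contact_loop[1] + 1))
        return [chain, partner], form, truth
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Relaxation


def relaxation_truth(spec: SyntheticSpec) -> pd.DataFrame:
    """Per-residue ground-truth (R1, R2, NOE) profile."""
    loops = spec.loop_set()
    rows = []
    for res in range(1, spec.chain_length + 1):
        terminal = res <= 3 or res >= spec.chain_length - 2
        mobile = res in loops or terminal
        rows.append({
            "residue": res,
            "r1": spec.r1_core * (spec.r1_loop_factor if mobile else 1.0),
            "r2": spec.r2_core * (spec.r2_loop_factor if mobile else 1.0),
            "noe": spec.noe_loop if mobile else spec.noe_core,
        })
    return pd.DataFrame(rows)


def make_relaxation(spec: SyntheticSpec, out_dir: str | Path | None = None):
    """R1/R2 decay series and duplicate NOE intensity tables (+ truths).

    Returns ``(r1_table, r2_table, noe_table, truth)`` as DataFrames in the
    documented CSV layouts; when ``out_dir`` is given they are also written
    as ``r1.csv``, ``r2.csv``, ``noe.csv``, ``relaxation_truth.csv``.
    """
    rng = spec.rng(2)
    truth = relaxation_truth(spec)
    tables = {}
    for name, delays, col in (("r1", R1_DELAYS, "r1"), ("r2", R2_DELAYS, "r2")):
        rows = []
        for _, t in truth.iterrows():
            i0 = 100.0
            clean = i0 * np.exp(-t[col] * delays)
            for rep in (1, 2):
                noisy = clean * (1.0 + rng.normal(0.0, spec.relax_noise,
                                                  size=len(delays)))
                for d, y in zip(delays, noisy):
                    rows.append({"residue": int(t["residue"]), "delay_s": d,
                                 "intensity": y, "replicate": rep})
        tables[name] = pd.DataFrame(rows)
    rows = []
    for _, t in truth.iterrows():
        i_off = 100.0
        for rep in (1, 2):
            on = t["noe"] * i_off * (1.0 + rng.normal(0.0, spec.relax_noise))
            off = i_off * (1.0 + rng.normal(0.0, spec.relax_noise))
            rows.append({"residue": int(t["residue"]), "i_on": on,
                         "i_off": off, "replicate": rep})
    tables["noe"] = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables["r1"].to_csv(out / "r1.csv", index=False)
        tables["r2"].to_csv(out / "r2.csv", index=False)
        tables["noe"].to_csv(out / "noe.csv", index=False)
        truth.to_csv(out / "relaxation_truth.csv", index=False)
    return tables["r1"], tables["r2"], tables["noe"], truth


# ---------------------------------------------------------------------------
# Titration


def make_titration(spec: SyntheticSpec, n_steps: int = 8,
                   out_dir: str | Path | None = None):
    """Free spectrum plus ``n_steps`` titration points to a 1:2 molar ratio.

    Fast exchange: observed shifts move linearly with the bound fraction,
    which saturates hyperbolically along the titration; site residues also
    lose cross-peak intensity.  The 1:1 analysis point is step
    ``n_steps - 3`` (step 5 of 8 by default).  Returns
    ``(free_df, [step dfs], truth dict)``.
    """
    rng = spec.rng(3)
    residues = np.arange(1, spec.chain_length + 1)
    free = pd.DataFrame({
        "residue": residues,
        "h_ppm": rng.uniform(7.0, 9.5, size=len(residues)),
        "n_ppm": rng.uniform(105.0, 130.0, size=len(residues)),
        "intensity": rng.uniform(0.8, 1.2, size=len(residues)),
    })
    site = set(spec.site_residues)
    # per-residue saturation endpoints (random sign pattern, site only)
    sign_h = rng.choice([-1.0, 1.0], size=len(residues))
    sign_n = rng.choice([-1.0, 1.0], size=len(residues))
    scale = rng.uniform(0.5, 1.0, size=len(residues))
    steps = []
    # bound fraction saturating along the titration; the 1:1 point (step
    # n_steps-3) sits at spec.saturation_1to1
    idx_1to1 = n_steps - 3
    fracs = spec.saturation_1to1 * (np.arange(1, n_steps + 1) / idx_1to1) \
        / (1.0 + (np.arange(1, n_steps + 1) - idx_1to1).clip(0) * 0.15)
    fracs = np.clip(fracs, 0.0, 0.95)
    for k in range(n_steps):
        f = fracs[k]
        df = free.copy()
        in_site = np.isin(df["residue"].to_numpy(), list(site))
        dd_h = np.where(in_site, sign_h * scale * spec.max_dd_h * f, 0.0)
        dd_n = np.where(in_site, sign_n * scale * spec.max_dd_n * f, 0.0)
        df["h_ppm"] = df["h_ppm"] + dd_h + rng.normal(0, spec.shift_noise,
                                                      len(df))
        df["n_ppm"] = df["n_ppm"] + dd_n + rng.normal(
            0, spec.shift_noise * 5, len(df))
        ratio = np.where(
            in_site,
            1.0 - f * (1.0 - spec.site_intensity_ratio) / spec.saturation_1to1,
            1.0 - f * (1.0 - spec.background_intensity_ratio)
            / spec.saturation_1to1,
        ).clip(0.05)
        df["intensity"] = free["intensity"] * ratio \
            * (1.0 + rng.normal(0, 0.02, len(df)))
        steps.append(df)
    truth = {"site_residues": sorted(site), "analysis_step": idx_1to1}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        free.to_csv(out / "titration_free.csv", index=False)
        for k, df in enumerate(steps, start=1):
            df.to_csv(out / f"titration_step{k}.csv", index=False)
        (out / "titration_truth.json").write_text(json.dumps(truth, indent=1))
    return free, steps, truth


# ---------------------------------------------------------------------------
# DLS


def make_correlogram(spec: SyntheticSpec, n_points: int = 200,
                     out_dir: str | Path | None = None) -> sb.Correlogram:
    """Siegert-relation correlogram for the spec's particle mixture."""
    rng = spec.rng(4)
    q = sb.scattering_vector(sb.DEFAULT_N0, sb.DEFAULT_WAVELENGTH,
                             sb.DEFAULT_ANGLE)
    eta = sb.water_viscosity(spec.temperature_k)
    gammas, fracs = [], []
    for rh_nm, frac in spec.dls_components:
        D = sb.K_B * spec.temperature_k / (6.0 * math.pi * eta * rh_nm * 1e-9)
        gammas.append(D * q ** 2)
        fracs.append(frac)
    fracs = np.asarray(fracs) / np.sum(fracs)
    tau = np.geomspace(1e-7, 1.0, n_points)
    g1 = sum(f * np.exp(-g * tau) for f, g in zip(fracs, gammas))
    decay = spec.dls_baseline * spec.dls_beta * g1 ** 2
    if spec.dls_noise > 0:
        decay = decay * (1.0 + rng.normal(0.0, spec.dls_noise, size=len(tau)))
    g2 = spec.dls_baseline + decay
    corr = sb.Correlogram(tau, g2, temperature_k=spec.temperature_k)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"tau_s": tau, "g2": g2}).to_csv(
            out / "correlogram.csv", index=False)
        truth = {"components": [list(x) for x in spec.dls_components],
                 "temperature_k": spec.temperature_k,
                 "baseline": spec.dls_baseline, "beta": spec.dls_beta}
        (out / "dls_truth.json").write_text(json.dumps(truth, indent=1))
    return corr


def read_correlogram(path: str, temperature_k: float = 293.0) -> sb.Correlogram:
    df = pd.read_csv(path, comment="#")
    return sb.Correlogram(df["tau_s"].to_numpy(), df["g2"].to_numpy(),
                          temperature_k=temperature_k)


# ---------------------------------------------------------------------------
# SAXS


def make_saxs(
    spec: SyntheticSpec,
    q: np.ndarray | None = None,
    out_dir: str | Path | None = None,
):
    """Guinier-regime curve, a candidate pool, and a noisy known mixture.

    Returns ``(guinier_curve, pool_curves, mixture_curve, truth)`` where the
    mixture combines the first ``len(spec.saxs_mixture)`` pool members with
    the spec's weights plus multiplicative Gaussian noise.
    """
    rng = spec.rng(5)
    if q is None:
        q = np.linspace(0.008, 0.30, 150)
    # Guinier synthetic: exact exponential + fractional noise
    ig = spec.saxs_i0 * np.exp(-(q * spec.saxs_rg) ** 2 / 3.0)
    noise = rng.normal(0.0, spec.saxs_noise, size=len(q))
    sigma_g = np.maximum(spec.saxs_noise * ig, 1e-12)
    guinier_curve = ScatteringCurve(q, ig * (1.0 + noise), sigma_g)

    # candidate pool: conformers with genuinely distinct global shapes
    # (varying solenoid compactness), as a model pool must be for a
    # minimal-ensemble search to be identifiable
    pool = []
    for k in range(spec.saxs_pool):
        radius = 6.0 + 1.2 * k
        rise = 1.8 - 0.08 * k
        template = _template_backbone(spec.chain_length, radius, rise)
        jitter = rng.normal(0.0, 0.3, size=(len(template), 3))
        residues = []
        for r, d in zip(template, jitter):
            residues.append(ResidueRecord(r.seq_num, r.aa, [
                Atom(a.name, a.x + d[0], a.y + d[1], a.z + d[2], a.b, a.occ)
                for a in r.atoms
            ]))
        model = MonomerModel(str(k + 1), "A", residues, "synthetic-saxs")
        pool.append(debye_curve(model, q))

    weights = np.asarray(spec.saxs_mixture, float)
    weights = weights / weights.sum()
    mix = sum(w * c.intensity for w, c in zip(weights, pool))
    sigma = np.maximum(0.01 * mix, 1e-12)
    mix_noisy = mix * (1.0 + rng.normal(0.0, 0.01, size=len(q)))
    mixture = ScatteringCurve(q, mix_noisy, sigma)
    truth = {"weights": weights.tolist(),
             "members": list(range(len(weights))),
             "rg": spec.saxs_rg, "i0": spec.saxs_i0}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_dat(guinier_curve, out / "saxs_guinier.dat")
        write_dat(mixture, out / "saxs_mixture.dat")
        for i, c in enumerate(pool):
            write_dat(c, out / f"saxs_pool_{i:02d}.dat")
        (out / "saxs_truth.json").write_text(json.dumps(truth, indent=1))
    return guinier_curve, pool, mixture, truth


# ---------------------------------------------------------------------------
# Fixture suite


def write_fixture_suite(spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Write every synthetic input kind plus a manifest JSON."""
    from .structure_io import write_ensemble

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ensemble, sigma = make_ensemble(spec)
    write_ensemble(ensemble, out / "ensemble.pdb")
    pd.DataFrame({"residue": list(sigma), "sigma": list(sigma.values())}) \
        .to_csv(out / "ensemble_truth.csv", index=False)
    make_relaxation(spec, out)
    make_titration(spec, out_dir=out)
    make_correlogram(spec, out_dir=out)
    make_saxs(spec, out_dir=out)
    manifest = {"spec": asdict(spec)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return out
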