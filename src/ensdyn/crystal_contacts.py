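"""Crystal lattice contacts and per-residue buried surface area.

Symmetry mates are generated from the unit cell and space group, contacting
copies are turned into chain-chain interfaces, interfaces that are images of
one another under the space group are reported once, and the solvent
accessible surface area (SASA) lost by each residue upon forming each
interface is summed into a per-chain burial profile.

SASA uses the Shrake-Rupley numerical scheme with a deterministic
golden-spiral point set (no RNG): an atom's accessible area is the fraction
of test points on its probe-expanded sphere that fall outside every
neighbouring expanded sphere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
import logging
from typing import Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import CrystalForm, MonomerModel

logger = logging.getLogger(__name__)

__all__ = [
    "VDW_RADII",
    "sasa",
    "symmetry_mates",
    "lattice_interfaces",
    "burial_profile",
    "ContactInterface",
    "BurialProfile",
]

# Bondi van der Waals radii (A), keyed by element.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90,
}
DEFAULT_RADIUS = 1.70
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960
DEFAULT_CUTOFF = 5.0  # A, heavy-atom center distance defining "contacting"


def element_of(atom_name: str) -> str:
    """Element guess from a PDB-style atom name (CA -> C, NZ -> N, ...)."""
    name = atom_name.strip()
    if name[:2].upper() in ("SE", "CL", "BR"):
        return name[:2].upper()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _golden_spiral(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (Fibonacci / golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)],
        axis=1,
    )


def _flatten(models: MonomerModel | Sequence[MonomerModel]):
    if isinstance(models, MonomerModel):
        models = [models]
    coords, radii, owner = [], [], []  # owner: (model index, seq_num)
    for mi, m in enumerate(models):
        for r in m.residues:
            for a in r.atoms:
                el = element_of(a.name)
                if el == "H":
                    continue
                rad = VDW_RADII.get(el)
                if rad is None:
                    logger.warning("unknown element %r, using %.2f A", el,
                                   DEFAULT_RADIUS)
                    rad = DEFAULT_RADIUS
                coords.append((a.x, a.y, a.z))
                radii.append(rad)
                owner.append((mi, r.seq_num))
    return list(models), np.asarray(coords), np.asarray(radii), owner


@dataclass
class SASAResult:
    total: float
    per_atom: np.ndarray
    per_residue: list[dict[int, float]]  # one {seq_num: area} map per model


def sasa(
    models: MonomerModel | Sequence[MonomerModel],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SASAResult:
    """Shrake-Rupley SASA of one model or a multi-chain assembly (A^2)."""
    model_list, xyz, radii, owner = _flatten(models)
    if len(xyz) == 0:
        raise ValueError("no heavy atoms")
    sphere = _golden_spiral(n_points)
    expanded = radii + probe
    tree = cKDTree(xyz)
    max_reach = 2.0 * expanded.max()
    per_atom = np.zeros(len(xyz))
    for i in range(len(xyz)):
        pts = xyz[i] + expanded[i] * sphere
        neigh = tree.query_ball_point(xyz[i], expanded[i] + expanded.max())
        neigh = [j for j in neigh if j != i]
        accessible = np.ones(n_points, dtype=bool)
        if neigh:
            nxyz = xyz[neigh]
            nrad = expanded[neigh]
            d2 = ((pts[:, None, :] - nxyz[None, :, :]) ** 2).sum(axis=2)
            accessible = (d2 >= (nrad ** 2)[None, :]).all(axis=1)
        per_atom[i] = (
            4.0 * np.pi * expanded[i] ** 2 * accessible.sum() / n_points
        )
    per_res: list[dict[int, float]] = [dict() for _ in model_list]
    for area, (mi, seq) in zip(per_atom, owner):
        per_res[mi][seq] = per_res[mi].get(seq, 0.0) + area
    return SASAResult(total=float(per_atom.sum()), per_atom=per_atom,
                      per_residue=per_res)


# ---------------------------------------------------------------------------
# Symmetry


class SpaceGroupError(ValueError):
    pass


def _space_group_ops(symbol: str) -> list[gemmi.Op]:
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise SpaceGroupError(
            f"unsupported space group {symbol!r}; use a Hermann-Mauguin "
            "symbol such as 'P 1', 'P 21 21 21' or 'C 2 2 21'"
        )
    return list(sg.operations())


def _op_matrices(op: gemmi.Op) -> tuple[np.ndarray, np.ndarray]:
    R = np.asarray(op.rot, float) / gemmi.Op.DEN
    t = np.asarray(op.tran, float) / gemmi.Op.DEN
    return R, t


@dataclass
class SymmetryMate:
    model: MonomerModel
    source_index: int  # index of the ASU chain this is a copy of
    op_index: int
    op_triplet: str
    lattice_shift: tuple[int, int, int]
    min_distance: float


def _transform_model(model: MonomerModel, cell: gemmi.UnitCell,
                     R_frac: np.ndarray, t_frac: np.ndarray,
                     tag: str) -> MonomerModel:
    O = np.asarray(cell.orth.mat.tolist(), float)
    F = np.asarray(cell.frac.mat.tolist(), float)
    R_cart = O @ R_frac @ F
    t_cart = O @ t_frac
    return model.transformed(R_cart, t_cart, model_id=f"{model.model_id}{tag}")


def symmetry_mates(
    model: MonomerModel,
    form: CrystalForm,
    cutoff: float = DEFAULT_CUTOFF,
    source_models: Sequence[MonomerModel] | None = None,
) -> list[SymmetryMate]:
    """Symmetry/lattice copies with >= 1 atom pair within ``cutoff`` of ``model``.

    Copies of ``model`` itself (or of every chain in ``source_models``) are
    enumerated over the space-group operators times lattice translations in
    {-1, 0, 1}^3; the identity copy is excluded.
    """
    ops = _space_group_ops(form.space_group)
    cell = form.gemmi_cell()
    _, ref_xyz, _, _ = _flatten(model)
    tree = cKDTree(ref_xyz)
    sources = list(source_models) if source_models is not None else [model]
    mates: list[SymmetryMate] = []
    for si, src in enumerate(sources):
        _, src_xyz, _, _ = _flatten(src)
        O = np.asarray(cell.orth.mat.tolist(), float)
        F = np.asarray(cell.frac.mat.tolist(), float)
        frac = src_xyz @ F.T
        for oi, op in enumerate(ops):
            R, t = _op_matrices(op)
            base = frac @ R.T + t
            for shift in itertools.product((-1, 0, 1), repeat=3):
                is_identity = (
                    src is model
                    and np.allclose(R, np.eye(3))
                    and np.allclose(t + np.asarray(shift), 0.0)
                )
                if is_identity:
                    continue
                cart = (base + np.asarray(shift, float)) @ O.T
                d, _ = tree.query(cart, k=1)
                dmin = float(d.min())
                if dmin <= cutoff:
                    mate = _transform_model(
                        src, cell, R, t + np.asarray(shift, float),
                        tag=f"~{oi}{shift}",
                    )
                    mates.append(SymmetryMate(mate, si, oi, op.triplet(),
                                              shift, dmin))
    return mates


# ---------------------------------------------------------------------------
# Interfaces


@dataclass
class ContactInterface:
    chain_id: str
    partner_chain_id: str
    op_triplet: str
    lattice_shift: tuple[int, int, int]
    intra_asu: bool
    burial: dict[int, float]          # per-residue A^2 on chain_id's side
    partner_burial: dict[int, float]  # per-residue A^2 on the partner's side

    @property
    def total(self) -> float:
        return sum(self.burial.values())


def _canonical_key(ci: str, cj: str, R: np.ndarray, v: np.ndarray):
    """Interface identity modulo viewing direction and lattice conjugation.

    The pair (chain_i, g.chain_j) viewed from chain_j is
    (chain_j, g^-1.chain_i); conjugating the whole pair by a lattice
    translation s maps (g, v) to (g, v + (I - R_g) s).  The key is the
    lexicographic minimum over both views and s in {-1,0,1}^3.
    """
    Rinv = np.linalg.inv(R)
    vinv = -Rinv @ v
    candidates = []
    for (a, b, RR, vv) in ((ci, cj, R, v), (cj, ci, Rinv, vinv)):
        for s in itertools.product((-1, 0, 1), repeat=3):
            vs = vv + (np.eye(3) - RR) @ np.asarray(s, float)
            candidates.append(
                (a, b,
                 tuple(np.round(RR.flatten(), 6)),
                 tuple(np.round(vs, 6)))
            )
    return min(candidates)


def lattice_interfaces(
    chains: Sequence[MonomerModel],
    form: CrystalForm,
    cutoff: float = DEFAULT_CUTOFF,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> list[ContactInterface]:
    """Unique chain-chain contact interfaces of one crystal.

    For every chain and every contacting partner copy, the per-residue buried
    area is SASA(chain alone) - SASA(chain in the pair).  Interfaces between
    chains of the same asymmetric unit (the biological dimer interface) are
    included but flagged ``intra_asu`` so lattice-only profiles can drop
    them.  Interfaces equivalent under the space group are reported once,
    carrying burial maps for both participating chains.
    """
    iso = {c.chain_id: sasa(c, probe, n_points) for c in chains}
    seen = set()
    out: list[ContactInterface] = []

    def burial_maps(center: MonomerModel, partner: MonomerModel):
        pair = sasa([center, partner], probe, n_points)
        bc, bp = {}, {}
        iso_c = iso[center.chain_id].per_residue[0]
        iso_p = iso[partner.chain_id].per_residue[0]
        for seq, area in pair.per_residue[0].items():
            d = iso_c[seq] - area
            if d > 1e-9:
                bc[seq] = d
        for seq, area in pair.per_residue[1].items():
            d = iso_p[seq] - area
            if d > 1e-9:
                bp[seq] = d
        return bc, bp

    for ci, chain in enumerate(chains):
        for mate in symmetry_mates(chain, form, cutoff, source_models=chains):
            partner_src = chains[mate.source_index]
            R, t = _op_matrices(_space_group_ops(form.space_group)[mate.op_index])
            v = t + np.asarray(mate.lattice_shift, float)
            intra = (
                mate.op_index == 0
                and mate.lattice_shift == (0, 0, 0)
                and mate.source_index != ci
            )
            key = _canonical_key(chain.chain_id, partner_src.chain_id, R, v)
            if key in seen:
                continue
            seen.add(key)
            bc, bp = burial_maps(chain, mate.model)
            if not bc and not bp:
                continue
            out.append(ContactInterface(
                chain_id=chain.chain_id,
                partner_chain_id=partner_src.chain_id,
                op_triplet=mate.op_triplet,
                lattice_shift=mate.lattice_shift,
                intra_asu=intra,
                burial=bc,
                partner_burial=bp,
            ))
    return out


@dataclass
class BurialProfile:
    chain_id: str
    seq_nums: np.ndarray
    buried: np.ndarray  # A^2, summed over unique interfaces

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.seq_nums.tolist(), self.buried.tolist()))


def burial_profile(
    interfaces: Sequence[ContactInterface],
    chain_id: str,
    seq_nums: Sequence[int] | None = None,
    lattice_only: bool = False,
) -> BurialProfile:
    """Sum per-residue buried area over one chain's unique interfaces.

    A chain participates in an interface record either as ``chain_id`` (its
    ``burial`` map) or as the partner (``partner_burial``); self-contacts
    through the lattice contribute both maps, covering both faces of the
    central copy.
    """
    relevant = [
        i for i in interfaces
        if chain_id in (i.chain_id, i.partner_chain_id)
        and not (lattice_only and i.intra_asu)
    ]
    if not relevant and not any(
        chain_id in (i.chain_id, i.partner_chain_id) for i in interfaces
    ) and interfaces:
        raise ValueError(f"chain {chain_id!r} not present in any interface")
    acc: dict[int, float] = {}
    for itf in relevant:
        if itf.chain_id == chain_id:
            for seq, a in itf.burial.items():
                acc[seq] = acc.get(seq, 0.0) + a
        if itf.partner_chain_id == chain_id:
            for seq, a in itf.partner_burial.items():
                acc[seq] = acc.get(seq, 0.0) + a
    if seq_nums is None:
        seq_nums = sorted(acc)
    arr = np.array([acc.get(n, 0.0) for n in seq_nums])
    return BurialProfile(chain_id, np.asarray(list(seq_nums)), arr)
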