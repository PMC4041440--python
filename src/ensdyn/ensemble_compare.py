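"""Superposition and per-residue RMSD profiling of structural ensembles.

An "ensemble" here is any set of monomer models of the same chain: the
crystallographically independent copies from one or more crystal forms, an
NMR model set, or a synthetic ensemble.  Members are compared pairwise after
a global least-squares (Kabsch) superposition on a masked backbone region;
residue-level divergence is then summarized as mean/min/max over the pairs,
with a fixed placeholder value standing in whenever a residue lacks
coordinates in either member of a pair, so that unmodeled (disordered)
residues show up as maximal divergence rather than silently vanishing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structure_io import BACKBONE_ATOMS, MonomerModel, StructureEnsemble

__all__ = [
    "RegionMask",
    "SuperpositionResult",
    "RMSDProfile",
    "kabsch_superpose",
    "pairwise_rmsd_matrix",
    "per_residue_profile",
    "rmsd_to_mean",
    "DEFAULT_MASK",
]

DEFAULT_PLACEHOLDER = 10.0  # Angstrom, for residues unmodeled in a pair


class SuperpositionError(ValueError):
    """Too few or degenerate atom pairs for a least-squares superposition."""


@dataclass(frozen=True)
class RegionMask:
    """Sorted, non-overlapping closed residue intervals (author numbering)."""

    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        ivs = tuple(sorted((int(a), int(b)) for a, b in self.intervals))
        for (a, b) in ivs:
            if b < a:
                raise ValueError(f"empty interval {a}-{b}")
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 <= b1:
                raise ValueError("mask intervals overlap")
        object.__setattr__(self, "intervals", ivs)

    def __contains__(self, seq_num: int) -> bool:
        return any(a <= seq_num <= b for a, b in self.intervals)


#: Ordered-core mask excluding the flexible termini and the two mobile loops
#: between strands S3-S4 and S4-S5.
DEFAULT_MASK = RegionMask(((1, 47), (56, 112)))


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # applied after rotation
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _paired_coords(
    mobile: MonomerModel,
    reference: MonomerModel,
    atom_set: Sequence[str],
    mask: RegionMask | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates paired by (seq_num, atom name) over shared residues."""
    ref_index = {}
    for r in reference.residues:
        if mask is None or r.seq_num in mask:
            for a in r.atoms:
                if a.name in atom_set:
                    ref_index[(r.seq_num, a.name)] = (a.x, a.y, a.z)
    xs, ys = [], []
    for r in mobile.residues:
        if mask is None or r.seq_num in mask:
            for a in r.atoms:
                key = (r.seq_num, a.name)
                if a.name in atom_set and key in ref_index:
                    xs.append((a.x, a.y, a.z))
                    ys.append(ref_index[key])
    return np.asarray(xs, float), np.asarray(ys, float)


def kabsch_superpose(
    mobile: MonomerModel,
    reference: MonomerModel,
    atom_set: Sequence[str] = BACKBONE_ATOMS,
    mask: RegionMask | None = None,
) -> SuperpositionResult:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Atoms are paired by residue number and atom name on residues present in
    both models (restricted to ``mask`` when given).  Returns the proper
    rotation minimizing the RMSD; a reflection is never returned.
    """
    x, y = _paired_coords(mobile, reference, atom_set, mask)
    if len(x) < 3:
        raise SuperpositionError(f"only {len(x)} paired atoms (need >= 3)")
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    s = np.linalg.svd(x0, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise SuperpositionError("paired atoms are (near-)collinear")
    H = x0.T @ y0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = x0 @ R.T - y0
    rmsd = float(np.sqrt((diff ** 2).sum() / len(x)))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=len(x))


def _pair_list(
    ensemble_a: StructureEnsemble, ensemble_b: StructureEnsemble | None
) -> tuple[StructureEnsemble, list[tuple[int, int]], bool]:
    """Ordered cross pairs, or unordered distinct pairs within one ensemble."""
    if ensemble_b is None or ensemble_b is ensemble_a:
        n = len(ensemble_a)
        return ensemble_a, [(i, j) for i in range(n) for j in range(i + 1, n)], True
    return ensemble_b, [
        (i, j) for i in range(len(ensemble_a)) for j in range(len(ensemble_b))
    ], False


def pairwise_rmsd_matrix(
    ensemble_a: StructureEnsemble,
    ensemble_b: StructureEnsemble | None = None,
    atom_set: Sequence[str] = BACKBONE_ATOMS,
    mask: RegionMask | None = DEFAULT_MASK,
) -> np.ndarray:
    """Matrix of global RMSDs after pairwise superposition.

    Entry (i, j) is the RMSD of member i of ``ensemble_a`` superposed onto
    member j of ``ensemble_b`` over the atoms present in both.  Within a
    single ensemble the matrix is symmetric with a zero diagonal.  Pairs with
    no usable overlap yield NaN.
    """
    within = ensemble_b is None or ensemble_b is ensemble_a
    b = ensemble_a if within else ensemble_b
    out = np.full((len(ensemble_a), len(b)), np.nan)
    for i, mi in enumerate(ensemble_a.members):
        for j, mj in enumerate(b.members):
            if within and j <= i:
                continue
            try:
                out[i, j] = kabsch_superpose(mi, mj, atom_set, mask).rmsd
            except SuperpositionError:
                continue
        if within:
            out[i, i] = 0.0
    if within:
        iu = np.triu_indices(len(out), k=1)
        out[(iu[1], iu[0])] = out[iu]
    return out


@dataclass
class RMSDProfile:
    seq_nums: np.ndarray
    mean: np.ndarray
    min: np.ndarray
    max: np.ndarray
    n_pairs_with_placeholder: np.ndarray
    placeholder: float
    n_pairs: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "seq_num": self.seq_nums,
                "mean": self.mean,
                "min": self.min,
                "max": self.max,
                "n_pairs_with_placeholder": self.n_pairs_with_placeholder,
            }
        ).set_index("seq_num")


def per_residue_profile(
    ensemble_a: StructureEnsemble,
    ensemble_b: StructureEnsemble | None = None,
    atom_set: Sequence[str] = BACKBONE_ATOMS,
    mask: RegionMask | None = DEFAULT_MASK,
    placeholder: float = DEFAULT_PLACEHOLDER,
) -> RMSDProfile:
    """Per-residue mean/min/max RMSD track over all member pairs.

    For each pair, members are first superposed globally on the masked
    backbone, then the RMSD is evaluated residue by residue over
    ``atom_set``.  A residue lacking coordinates in either member of a pair
    contributes ``placeholder`` (10 A by convention) for that pair, so
    disorder registers as divergence.
    """
    b, pairs, _ = _pair_list(ensemble_a, ensemble_b)
    all_nums = sorted(
        {n for m in ensemble_a for n in m.seq_nums}
        | {n for m in b for n in m.seq_nums}
    )
    idx = {n: k for k, n in enumerate(all_nums)}
    values = np.full((len(pairs), len(all_nums)), placeholder)
    used_placeholder = np.ones((len(pairs), len(all_nums)), dtype=bool)
    for p, (i, j) in enumerate(pairs):
        mi, mj = ensemble_a.members[i], b.members[j]
        sup = kabsch_superpose(mi, mj, atom_set, mask)
        res_j = {r.seq_num: r for r in mj.residues}
        for r in mi.residues:
            other = res_j.get(r.seq_num)
            if other is None:
                continue
            xi = [a for a in r.atoms if a.name in atom_set]
            names = [a.name for a in xi]
            xj = [other.atom(n) for n in names]
            paired = [(a, bb) for a, bb in zip(xi, xj) if bb is not None]
            if not paired:
                continue
            xa = np.array([[a.x, a.y, a.z] for a, _ in paired])
            xb = np.array([[bb.x, bb.y, bb.z] for _, bb in paired])
            diff = sup.apply(xa) - xb
            k = idx[r.seq_num]
            values[p, k] = float(np.sqrt((diff ** 2).sum() / len(paired)))
            used_placeholder[p, k] = False
    return RMSDProfile(
        seq_nums=np.asarray(all_nums),
        mean=values.mean(axis=0),
        min=values.min(axis=0),
        max=values.max(axis=0),
        n_pairs_with_placeholder=used_placeholder.sum(axis=0),
        placeholder=placeholder,
        n_pairs=len(pairs),
    )


def rmsd_to_mean(
    ensemble: StructureEnsemble,
    atom_set: Sequence[str] = BACKBONE_ATOMS,
    mask: RegionMask | None = DEFAULT_MASK,
    n_passes: int = 2,
    min_coverage: float = 0.5,
) -> tuple[list[float], float, float]:
    """RMSD of each member to the iteratively refined coordinate average.

    All members are superposed onto the running average structure (first
    member as the initial reference), the average is recomputed from the
    fitted coordinates, and the superpose/average cycle is repeated
    ``n_passes`` times.  Atoms modeled in fewer than ``min_coverage`` of the
    members are excluded from the average.  Returns
    ``(per-member RMSDs, mean, sd)``.
    """
    if len(ensemble) < 2:
        raise ValueError("need >= 2 members")
    members = ensemble.members
    # collect atom keys eligible for the average structure
    counts: dict[tuple[int, str], int] = {}
    for m in members:
        keys, _ = m.atom_coords(atom_set)
        for key in keys:
            if mask is None or key[0] in mask:
                counts[key] = counts.get(key, 0) + 1
    avg_keys = sorted(k for k, c in counts.items() if c >= min_coverage * len(members))
    if len(avg_keys) < 3:
        raise ValueError("too few well-covered atoms for an average structure")
    key_idx = {k: i for i, k in enumerate(avg_keys)}

    def member_rows(m: MonomerModel) -> tuple[np.ndarray, np.ndarray]:
        rows, xyz = [], []
        for r in m.residues:
            for a in r.atoms:
                i = key_idx.get((r.seq_num, a.name))
                if i is not None:
                    rows.append(i)
                    xyz.append([a.x, a.y, a.z])
        return np.asarray(rows), np.asarray(xyz, float)

    rows_xyz = [member_rows(m) for m in members]
    fitted = [xyz.copy() for _, xyz in rows_xyz]

    def fit_all_onto(avg: np.ndarray) -> None:
        for k, (rows, xyz) in enumerate(rows_xyz):
            x, y = xyz, avg[rows]
            xc, yc = x.mean(axis=0), y.mean(axis=0)
            H = (x - xc).T @ (y - yc)
            U, _, Vt = np.linalg.svd(H)
            d = np.sign(np.linalg.det(Vt.T @ U.T))
            R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
            fitted[k] = (x - xc) @ R.T + yc

    def compute_avg() -> np.ndarray:
        acc = np.zeros((len(avg_keys), 3))
        n = np.zeros(len(avg_keys))
        for (rows, _), f in zip(rows_xyz, fitted):
            acc[rows] += f
            n[rows] += 1
        return acc / n[:, None]

    # initial reference: first member's coordinates on the average grid
    avg = np.zeros((len(avg_keys), 3))
    seen = np.zeros(len(avg_keys), dtype=bool)
    rows0, xyz0 = rows_xyz[0]
    avg[rows0] = xyz0
    seen[rows0] = True
    if not seen.all():
        # fill gaps from the raw mean of whoever models them
        acc = np.zeros((len(avg_keys), 3))
        n = np.zeros(len(avg_keys))
        for rows, xyz in rows_xyz:
            acc[rows] += xyz
            n[rows] += 1
        fill = ~seen
        avg[fill] = acc[fill] / n[fill, None]

    for _ in range(n_passes + 1):
        fit_all_onto(avg)
        avg = compute_avg()

    rmsds = []
    for (rows, _), f in zip(rows_xyz, fitted):
        diff = f - avg[rows]
        rmsds.append(float(np.sqrt((diff ** 2).sum() / len(rows))))
    arr = np.asarray(rmsds)
    return rmsds, float(arr.mean()), float(arr.std(ddof=1))
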