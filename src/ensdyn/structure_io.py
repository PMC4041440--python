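"""Coordinate I/O, ensemble assembly and sequence/cell-derived constants.

Coordinates are handled in author numbering throughout: a purification tag
occupies seq_num <= 0 and the mature chain starts at 1.  Ensembles are flat
lists of monomers -- one :class:`MonomerModel` per (file, model, chain) --
because all downstream comparisons treat crystallographically independent
copies and NMR models on the same footing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "ResidueRecord",
    "MonomerModel",
    "StructureEnsemble",
    "ExpectedConstruct",
    "CrystalForm",
    "read_ensemble",
    "write_ensemble",
    "missing_residues",
    "extinction_coefficient",
    "average_mass",
    "matthews",
    "bfactor_profile",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
]


class StructureFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed or is inconsistent."""


AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# Average (isotope-abundance weighted) residue masses in Da, i.e. the amino
# acid minus one water; a single water is added back per chain.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01528

# Pace molar absorption coefficients at 280 nm, M^-1 cm^-1.
EPS_TRP = 5500.0
EPS_TYR = 1490.0
EPS_CYSTINE = 125.0

# 1 - solvent_fraction = 1.23 / V_M for a protein partial specific volume
# of 0.74 cm^3/g (Matthews convention).
MATTHEWS_CONSTANT = 1.23

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class Atom(NamedTuple):
    name: str
    x: float
    y: float
    z: float
    b: float = 0.0
    occ: float = 1.0

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class ResidueRecord:
    seq_num: int
    aa: str
    atoms: list[Atom]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, atom_set: Sequence[str] | None = None) -> np.ndarray:
        atoms = self.atoms if atom_set is None else [
            a for n in atom_set for a in self.atoms if a.name == n
        ]
        return np.array([[a.x, a.y, a.z] for a in atoms], dtype=float)


@dataclass
class MonomerModel:
    model_id: str
    chain_id: str
    residues: list[ResidueRecord]
    source: str = ""

    def __post_init__(self) -> None:
        nums = [r.seq_num for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError(
                f"residue numbers not strictly increasing in {self.label}"
            )

    @property
    def label(self) -> str:
        return f"{self.model_id}/{self.chain_id}"

    @property
    def seq_nums(self) -> list[int]:
        return [r.seq_num for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def residue(self, seq_num: int) -> ResidueRecord | None:
        for r in self.residues:
            if r.seq_num == seq_num:
                return r
        return None

    def atom_coords(
        self, atom_set: Sequence[str] | None = None
    ) -> tuple[list[tuple[int, str]], np.ndarray]:
        """Flat (seq_num, atom name) keys and an (n, 3) coordinate array."""
        keys: list[tuple[int, str]] = []
        xyz: list[list[float]] = []
        for r in self.residues:
            for a in r.atoms:
                if atom_set is None or a.name in atom_set:
                    keys.append((r.seq_num, a.name))
                    xyz.append([a.x, a.y, a.z])
        return keys, np.asarray(xyz, dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    model_id: str | None = None) -> "MonomerModel":
        """Copy with coordinates mapped through x -> R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        residues = []
        for r in self.residues:
            atoms = []
            for a in r.atoms:
                v = R @ np.array([a.x, a.y, a.z]) + t
                atoms.append(Atom(a.name, v[0], v[1], v[2], a.b, a.occ))
            residues.append(ResidueRecord(r.seq_num, r.aa, atoms))
        return MonomerModel(model_id or self.model_id, self.chain_id,
                            residues, self.source)


@dataclass
class StructureEnsemble:
    members: list[MonomerModel]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must contain at least one member")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


@dataclass
class ExpectedConstruct:
    """The protein sequence the sample should contain, in author numbering."""

    sequence: str
    first_seq_num: int = 1
    notes: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(AVERAGE_RESIDUE_MASS)
        if bad:
            raise ValueError(f"non-standard residue code(s): {sorted(bad)}")

    @property
    def seq_nums(self) -> range:
        return range(self.first_seq_num, self.first_seq_num + len(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CrystalForm:
    cell_a: float
    cell_b: float
    cell_c: float
    cell_alpha: float = 90.0
    cell_beta: float = 90.0
    cell_gamma: float = 90.0
    space_group: str = "P 1"
    z_asu: int = 1
    asu_mass: float = 0.0  # Da of polymer per asymmetric unit

    def __post_init__(self) -> None:
        if min(self.cell_a, self.cell_b, self.cell_c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.cell_alpha, self.cell_beta, self.cell_gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")

    @property
    def cell_volume(self) -> float:
        """Unit-cell volume in A^3 (general triclinic formula)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in
                      (self.cell_alpha, self.cell_beta, self.cell_gamma))
        factor = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return self.cell_a * self.cell_b * self.cell_c * math.sqrt(factor)

    def gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.cell_a, self.cell_b, self.cell_c,
                              self.cell_alpha, self.cell_beta, self.cell_gamma)


# ---------------------------------------------------------------------------
# Reading / writing


def _collapse_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties to file order."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ + 1e-9:
            best[atom.name] = atom
    # preserve file order of the chosen atoms
    chosen = set(id(a) for a in best.values())
    return [a for a in res if id(a) in chosen]


def read_ensemble(
    paths: Iterable[str],
    selector: str | None = None,
    label: str = "",
) -> StructureEnsemble:
    """Assemble an ensemble of monomers from PDB / mmCIF files.

    Parameters
    ----------
    paths
        Coordinate files; every model and chain in each file becomes a
        candidate member.
    selector
        ``None``/``"all"`` keeps everything.  ``"A"`` keeps chain A from all
        models; ``"1/A"`` keeps chain A of model 1; a comma-separated list
        combines selections (``"1/A,2/B"``).
    """
    wanted: list[tuple[str | None, str | None]] = []
    if selector and selector != "all":
        for part in selector.split(","):
            part = part.strip()
            if "/" in part:
                m, c = part.split("/", 1)
                wanted.append((m or None, c or None))
            else:
                wanted.append((None, part))

    members: list[MonomerModel] = []
    for path in paths:
        try:
            st = gemmi.read_structure(str(path))
        except (RuntimeError, ValueError) as exc:
            raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
        st.setup_entities()
        n_dropped = 0
        for model in st:
            for chain in model:
                if wanted and not any(
                    (m is None or m == str(model.num)) and (c is None or c == chain.name)
                    for m, c in wanted
                ):
                    continue
                residues: list[ResidueRecord] = []
                for res in chain:
                    aa = AA3_TO_1.get(res.name)
                    if aa is None or res.het_flag == "H":
                        n_dropped += 1
                        continue
                    atoms = [
                        Atom(a.name, a.pos.x, a.pos.y, a.pos.z, a.b_iso, a.occ)
                        for a in _collapse_altlocs(res)
                    ]
                    if atoms:
                        residues.append(ResidueRecord(res.seqid.num, aa, atoms))
                if residues:
                    members.append(MonomerModel(
                        model_id=str(model.num),
                        chain_id=chain.name,
                        residues=residues,
                        source=f"{path}#{model.num}/{chain.name}",
                    ))
        if n_dropped:
            logger.info("%s: dropped %d non-standard/HETATM residues",
                        path, n_dropped)
    if not members:
        raise ValueError(f"no monomers selected (selector={selector!r})")
    return StructureEnsemble(members, label=label)


def write_ensemble(ensemble: StructureEnsemble, path: str) -> None:
    """Write every member as one MODEL of a multi-model PDB file."""
    with open(path, "w") as fh:
        for i, member in enumerate(ensemble, start=1):
            fh.write(f"MODEL     {i:4d}\n")
            serial = 1
            for res in member.residues:
                res3 = AA1_TO_3[res.aa]
                for a in res.atoms:
                    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                    fh.write(
                        f"ATOM  {serial:5d} {name:<4s} {res3} "
                        f"{member.chain_id[:1]}{res.seq_num:4d}    "
                        f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
                        f"{a.occ:6.2f}{a.b:6.2f}\n"
                    )
                    serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_fasta(construct: ExpectedConstruct, path: str, name: str = "construct") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name} first_res={construct.first_seq_num}\n")
        for i in range(0, len(construct.sequence), 60):
            fh.write(construct.sequence[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# Bookkeeping / derived constants


def missing_residues(
    model: MonomerModel, construct: ExpectedConstruct
) -> tuple[int, int, int]:
    """Partition residues absent from the model into (N-term, internal, C-term).

    The leading run of absent construct positions is the N-terminal count, the
    trailing run the C-terminal count, everything else internal; the triple
    always sums to ``len(construct) - len(model.residues)``.
    """
    construct_nums = list(construct.seq_nums)
    present = set(model.seq_nums)
    outside = present - set(construct_nums)
    if outside:
        raise ValueError(
            f"model residues {sorted(outside)} not covered by the construct"
        )
    absent = [n for n in construct_nums if n not in present]
    n_nterm = 0
    for n in construct_nums:
        if n in present:
            break
        n_nterm += 1
    n_cterm = 0
    for n in reversed(construct_nums):
        if n in present:
            break
        n_cterm += 1
    if n_nterm + n_cterm >= len(construct_nums):  # nothing modeled at all
        return len(construct_nums), 0, 0
    n_internal = len(absent) - n_nterm - n_cterm
    return n_nterm, n_internal, n_cterm


def extinction_coefficient(construct: ExpectedConstruct, n_cystine: int = 0) -> float:
    """Molar extinction coefficient at 280 nm (M^-1 cm^-1), Pace coefficients."""
    if n_cystine < 0:
        raise ValueError("n_cystine must be >= 0")
    n_trp = construct.sequence.count("W")
    n_tyr = construct.sequence.count("Y")
    return EPS_TRP * n_trp + EPS_TYR * n_tyr + EPS_CYSTINE * n_cystine


def average_mass(construct: ExpectedConstruct) -> float:
    """Average molecular mass in Da (residue masses plus one water)."""
    if not construct.sequence:
        raise ValueError("empty sequence")
    return sum(AVERAGE_RESIDUE_MASS[a] for a in construct.sequence) + WATER_MASS


def matthews(form: CrystalForm) -> tuple[float, float]:
    """Matthews coefficient V_M (A^3/Da) and solvent fraction.

    ``solvent = 1 - 1.23 / V_M`` (partial specific volume 0.74 cm^3/g).
    A solvent fraction outside (0, 1) is physically implausible and logged as
    a warning, but still returned.
    """
    if form.asu_mass <= 0 or form.z_asu <= 0:
        raise ValueError("z_asu and asu_mass must be positive")
    v_m = form.cell_volume / (form.z_asu * form.asu_mass)
    solvent = 1.0 - MATTHEWS_CONSTANT / v_m
    if not 0.0 < solvent < 1.0:
        logger.warning(
            "implausible solvent fraction %.3f (V_M = %.3f A^3/Da)", solvent, v_m
        )
    return v_m, solvent


def bfactor_profile(
    ensemble: StructureEnsemble,
    atom_set: Sequence[str] = BACKBONE_ATOMS,
) -> pd.DataFrame:
    """Per-residue mean B-factor of ``atom_set``, one column per member.

    Residues absent from a member are NaN, never 0; a ``mean`` column
    averages over the members that model each residue.
    """
    if not atom_set:
        raise ValueError("atom_set must be non-empty")
    all_nums = sorted({n for m in ensemble for n in m.seq_nums})
    data: dict[str, list[float]] = {}
    for member in ensemble:
        col = []
        for n in all_nums:
            res = member.residue(n)
            if res is None:
                col.append(np.nan)
            else:
                bs = [a.b for a in res.atoms if a.name in atom_set]
                col.append(float(np.mean(bs)) if bs else np.nan)
        data[member.label] = col
    df = pd.DataFrame(data, index=pd.Index(all_nums, name="seq_num"))
    df["mean"] = df.mean(axis=1)
    return df


def profile_to_tsv(df: pd.DataFrame, path: str, units: str = "A^2") -> None:
    """Write a per-residue profile table with a unit header comment."""
    with open(path, "w") as fh:
        fh.write(f"# per-residue profile; values in {units}\n")
        df.to_csv(fh, sep="\t", float_format="%.6g", na_rep="NA")
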