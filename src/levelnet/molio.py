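"""Molecular structure and eigenvalue-label I/O.

Structures travel as multi-frame XYZ (count line, comment line, ``El x y z``
records, coordinates in Å); eigenvalue labels as a CSV sidecar with header
``id,e0,...,e15`` holding the 16 highest occupied levels in eV, state 0 being
the HOMO. Molecules and labels are matched by string id, and molecules
without a full 16-level label row are dropped at assembly time — mirroring
the filter that discards molecules with fewer than sixteen occupied levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

logger = logging.getLogger(__name__)

N_LEVELS = 16

# Elements that occur in small organics; enough for the synthetic generator
# and the datasets this tool targets. Extend freely.
_SYMBOL_TO_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
}
_Z_TO_SYMBOL = {z: s for s, z in _SYMBOL_TO_Z.items()}


class ParseError(ValueError):
    """Malformed structure or label file; message names the offending line."""


@dataclass(frozen=True)
class Molecule:
    """A molecular geometry: atomic numbers Z_i and Cartesian positions R_i (Å)."""

    id: str
    atomic_numbers: np.ndarray  # (n,) int
    coordinates: np.ndarray     # (n, 3) float, Å

    def __post_init__(self) -> None:
        z = np.asarray(self.atomic_numbers, dtype=int)
        r = np.asarray(self.coordinates, dtype=float)
        if z.ndim != 1 or r.shape != (z.size, 3) or z.size < 1:
            raise ValueError(
                f"molecule {self.id!r}: need matching Z (n,) and R (n,3), "
                f"got {z.shape} and {r.shape}"
            )
        if not np.all(np.isfinite(r)):
            raise ValueError(f"molecule {self.id!r}: non-finite coordinates")
        if np.any(z < 1):
            raise ValueError(f"molecule {self.id!r}: atomic numbers must be >= 1")
        if z.size > 1:
            d = np.linalg.norm(r[:, None, :] - r[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() <= 0.0:
                raise ValueError(f"molecule {self.id!r}: coincident atoms")
        object.__setattr__(self, "atomic_numbers", z)
        object.__setattr__(self, "coordinates", r)

    @property
    def n_atoms(self) -> int:
        return int(self.atomic_numbers.size)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise distances in Å, zero diagonal."""
        r = self.coordinates
        return np.linalg.norm(r[:, None, :] - r[None, :, :], axis=-1)


@dataclass(frozen=True)
class LevelSet:
    """The 16 highest occupied eigenvalues (eV), descending; index 0 = HOMO."""

    molecule_id: str
    energies: np.ndarray  # (16,) float, eV

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.shape != (N_LEVELS,):
            raise ValueError(
                f"level set {self.molecule_id!r}: need exactly {N_LEVELS} "
                f"energies, got shape {e.shape}"
            )
        if np.any(np.diff(e) > 0):
            raise ValueError(
                f"level set {self.molecule_id!r}: energies must be descending "
                "(state 0 = HOMO)"
            )
        object.__setattr__(self, "energies", e)

    @property
    def homo(self) -> float:
        return float(self.energies[0])


@dataclass
class Dataset:
    """Matched (Molecule, LevelSet) records plus the padding size n_max."""

    records: list[tuple[Molecule, LevelSet]]
    n_max: int = field(default=0)
    n_dropped: int = field(default=0)

    def __post_init__(self) -> None:
        for mol, lev in self.records:
            if mol.id != lev.molecule_id:
                raise ValueError(f"record mismatch: {mol.id!r} vs {lev.molecule_id!r}")
        true_max = max((m.n_atoms for m, _ in self.records), default=0)
        if self.n_max == 0:
            self.n_max = true_max
        elif self.n_max < true_max:
            raise ValueError(f"n_max {self.n_max} < largest molecule {true_max}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def molecules(self) -> list[Molecule]:
        return [m for m, _ in self.records]

    @property
    def levels(self) -> np.ndarray:
        """(N, 16) array of label energies in record order."""
        return np.array([l.energies for _, l in self.records])

    @property
    def ids(self) -> list[str]:
        return [m.id for m, _ in self.records]

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset([self.records[i] for i in indices], n_max=self.n_max)


def read_xyz(path: str | Path) -> list[Molecule]:
    """Parse a (multi-frame) XYZ file into Molecules.

    The id of each frame is the first whitespace token of its comment line,
    or ``frame_<k>`` when the comment is blank.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    mols: list[Molecule] = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate blank separator lines
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}")
        if n < 1:
            raise ParseError(f"{path}:{i + 1}: invalid atom count {n}")
        if i + 2 + n > len(lines):
            raise ParseError(f"{path}:{i + 1}: frame truncated ({n} atoms declared)")
        comment = lines[i + 1].strip()
        mol_id = comment.split()[0] if comment else f"frame_{frame}"
        zs = np.empty(n, dtype=int)
        rs = np.empty((n, 3), dtype=float)
        for k in range(n):
            ln = i + 2 + k
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln + 1}: expected 'El x y z'")
            sym = parts[0]
            if sym in _SYMBOL_TO_Z:
                zs[k] = _SYMBOL_TO_Z[sym]
            elif sym.isdigit():
                zs[k] = int(sym)
            else:
                raise ParseError(f"{path}:{ln + 1}: unknown element {sym!r}")
            try:
                rs[k] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(f"{path}:{ln + 1}: non-numeric coordinate")
        mols.append(Molecule(mol_id, zs, rs))
        i += 2 + n
        frame += 1
    return mols


def write_xyz(mols: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules as a multi-frame XYZ file (id on the comment line)."""
    with open(path, "w") as fh:
        for mol in mols:
            fh.write(f"{mol.n_atoms}\n{mol.id}\n")
            for z, (x, y, zc) in zip(mol.atomic_numbers, mol.coordinates):
                sym = _Z_TO_SYMBOL.get(int(z), str(int(z)))
                fh.write(f"{sym} {x:.10f} {y:.10f} {zc:.10f}\n")


def read_levels(path: str | Path) -> list[LevelSet]:
    """Parse the ``id,e0,...,e15`` CSV of eigenvalue labels (eV).

    Rows whose energies are not already descending are re-sorted with a
    logged warning; a row with the wrong field count or a duplicated id is
    an error.
    """
    path = Path(path)
    out: list[LevelSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("id,"):
            raise ParseError(f"{path}:1: expected header 'id,e0,...,e15'")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.strip().split(",")
            if len(parts) != N_LEVELS + 1:
                raise ParseError(
                    f"{path}:{ln}: expected id + {N_LEVELS} energies, "
                    f"got {len(parts) - 1}"
                )
            mol_id = parts[0]
            if mol_id in seen:
                raise ParseError(f"{path}:{ln}: duplicate id {mol_id!r}")
            seen.add(mol_id)
            try:
                e = np.array([float(p) for p in parts[1:]])
            except ValueError:
                raise ParseError(f"{path}:{ln}: non-numeric energy")
            if np.any(np.diff(e) > 0):
                logger.warning("%s:%d: energies for %r not descending; re-sorting",
                               path, ln, mol_id)
                e = np.sort(e)[::-1]
            out.append(LevelSet(mol_id, e))
    return out


def write_levels(levelsets: Iterable[LevelSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id," + ",".join(f"e{k}" for k in range(N_LEVELS)) + "\n")
        for ls in levelsets:
            fh.write(ls.molecule_id + ","
                     + ",".join(f"{e:.10f}" for e in ls.energies) + "\n")


def assemble_dataset(molecules: Sequence[Molecule],
                     levelsets: Sequence[LevelSet]) -> Dataset:
    """Match molecules to label rows by id; unlabeled molecules are dropped.

    A molecule with no label row stands for one with fewer than 16 occupied
    levels and is counted in ``n_dropped``.
    """
    by_id = {m.id: m for m in molecules}
    unknown = [l.molecule_id for l in levelsets if l.molecule_id not in by_id]
    if unknown:
        raise ValueError(f"label rows without a structure: {unknown[:5]}")
    records = [(by_id[l.molecule_id], l) for l in levelsets]
    if not records:
        raise ValueError("no molecules with 16 levels")
    n_dropped = len(molecules) - len(records)
    ds = Dataset(records)
    ds.n_dropped = n_dropped
    if n_dropped:
        logger.info("dropped %d unlabeled molecules (fewer than 16 levels)",
                    n_dropped)
    return ds


def save_dataset_h5(ds: Dataset, path: str | Path) -> None:
    """Cache a dataset as HDF5 (zero-padded coordinate/Z arrays + levels + ids)."""
    n = len(ds)
    coords = np.zeros((n, ds.n_max, 3))
    zs = np.zeros((n, ds.n_max), dtype=np.int64)
    for i, (mol, _) in enumerate(ds.records):
        coords[i, : mol.n_atoms] = mol.coordinates
        zs[i, : mol.n_atoms] = mol.atomic_numbers
    with h5py.File(path, "w") as f:
        f.create_dataset("coordinates", data=coords)
        f.create_dataset("atomic_numbers", data=zs)
        f.create_dataset("levels", data=ds.levels)
        f.create_dataset("ids", data=np.array(ds.ids, dtype=h5py.string_dtype()))


def load_dataset_h5(path: str | Path) -> Dataset:
    with h5py.File(path, "r") as f:
        coords = f["coordinates"][...]
        zs = f["atomic_numbers"][...]
        levels = f["levels"][...]
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["ids"][...]]
    records = []
    for i, mol_id in enumerate(ids):
        n = int(np.count_nonzero(zs[i]))
        mol = Molecule(mol_id, zs[i, :n], coords[i, :n])
        records.append((mol, LevelSet(mol_id, levels[i])))
    return Dataset(records)
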