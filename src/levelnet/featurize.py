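"""Molecular descriptors: the Coulomb matrix and expanded distance features.

The Coulomb matrix is C_ij = Z_i Z_j / |R_i - R_j| off the diagonal (atomic
units, distances in Bohr) and C_ii = 0.5 Z_i^2.4 on it — an encoding that is
invariant to rigid motions of the molecule but not to atom relabeling. For
the vector/image networks we canonicalize atom order by sorting rows and
columns by descending row norm. The distance-based network instead consumes
the raw interatomic distance matrix expanded on a Gaussian basis grid, which
is invariant to both rigid motions and (with sum pooling) atom order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molio import Molecule

ANGSTROM_TO_BOHR = 1.8897261254578281


@dataclass(frozen=True)
class CoulombMatrix:
    values: np.ndarray  # (n_max, n_max) symmetric, zero padding
    n_atoms: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"Coulomb matrix must be square, got {v.shape}")
        if self.n_atoms > v.shape[0]:
            raise ValueError("n_atoms exceeds matrix size")
        object.__setattr__(self, "values", v)

    @property
    def n_max(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class DistanceFeatures:
    """Pair distances (Å) and their Gaussian-basis expansion.

    expansion[i, j, g] = exp(-(d_ij - center_g)^2 / (2 width^2)) for i != j;
    diagonal expansion vectors are identically zero.
    """

    distances: np.ndarray  # (n, n) Å
    expansion: np.ndarray  # (n, n, G)
    centers: np.ndarray    # (G,) Å
    width: float


def coulomb_matrix(mol: Molecule, n_max: int) -> CoulombMatrix:
    """Build the zero-padded Coulomb matrix of ``mol`` (atomic units)."""
    n = mol.n_atoms
    if n_max < n:
        raise ValueError(f"n_max={n_max} smaller than molecule ({n} atoms)")
    z = mol.atomic_numbers.astype(float)
    d_bohr = mol.distance_matrix() * ANGSTROM_TO_BOHR
    off = np.zeros((n, n))
    iu = ~np.eye(n, dtype=bool)
    if n > 1 and d_bohr[iu].min() <= 0.0:
        raise ValueError(f"molecule {mol.id!r}: coincident atoms")
    with np.errstate(divide="ignore"):
        off[iu] = np.outer(z, z)[iu] / d_bohr[iu]
    c = off
    c[np.diag_indices(n)] = 0.5 * z ** 2.4
    full = np.zeros((n_max, n_max))
    full[:n, :n] = c
    return CoulombMatrix(full, n)


def sort_coulomb(cm: CoulombMatrix) -> CoulombMatrix:
    """Canonical atom ordering: simultaneous row/column sort by row norm.

    Order is non-increasing Euclidean row norm; ties break by descending
    diagonal value, then by original index (stable). Padding stays last.
    """
    n = cm.n_atoms
    block = cm.values[:n, :n]
    norms = np.linalg.norm(block, axis=1)
    diags = np.diag(block)
    # lexsort's last key is primary; negate for descending order
    order = np.lexsort((np.arange(n), -diags, -norms))
    out = np.zeros_like(cm.values)
    out[:n, :n] = block[np.ix_(order, order)]
    return CoulombMatrix(out, n)


def flatten_upper(cm: CoulombMatrix) -> np.ndarray:
    """Row-major upper triangle (with diagonal); length n_max(n_max+1)/2."""
    iu = np.triu_indices(cm.n_max)
    return cm.values[iu].copy()


def unflatten_upper(vec: np.ndarray, n_max: int) -> np.ndarray:
    """Inverse of :func:`flatten_upper`, reconstructing the symmetric matrix."""
    vec = np.asarray(vec, dtype=float)
    expect = n_max * (n_max + 1) // 2
    if vec.size != expect:
        raise ValueError(f"expected length {expect}, got {vec.size}")
    out = np.zeros((n_max, n_max))
    iu = np.triu_indices(n_max)
    out[iu] = vec
    out = out + out.T - np.diag(np.diag(out))
    return out


def default_centers(r_min: float = 0.0, r_max: float = 4.0,
                    step: float = 0.2) -> np.ndarray:
    """Uniform Gaussian-center grid in Å (default 0–4 Å, step 0.2 Å)."""
    n = int(round((r_max - r_min) / step)) + 1
    return r_min + step * np.arange(n)


def expand_distances(mol: Molecule, centers: np.ndarray | None = None,
                     width: float = 0.2) -> DistanceFeatures:
    """Expand the pair-distance matrix on a Gaussian basis."""
    if width <= 0:
        raise ValueError("width must be positive")
    if centers is None:
        centers = default_centers()
    centers = np.asarray(centers, dtype=float)
    d = mol.distance_matrix()
    exp = np.exp(-((d[:, :, None] - centers[None, None, :]) ** 2)
                 / (2.0 * width ** 2))
    n = mol.n_atoms
    exp[np.arange(n), np.arange(n), :] = 0.0
    return DistanceFeatures(d, exp, centers, float(width))
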