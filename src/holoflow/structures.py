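"""Core domain types for apo/holo protein-ligand complexes.

Coordinates are in Angstroms throughout. Atom and residue indices are
0-based internally; 1-based numbering appears only in PDB serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


class InvalidInputError(ValueError):
    """Raised when a structure or graph violates its invariants."""


def _as_coords(a, name: str, n_rows: int | None = None) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise InvalidInputError(f"{name} must be an (N, 3) array, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite coordinates")
    if n_rows is not None and arr.shape[0] != n_rows:
        raise InvalidInputError(f"{name} must have {n_rows} rows, got {arr.shape[0]}")
    return arr


@dataclass(frozen=True)
class LigandGraph:
    """Bond graph of one or more ligand fragments (heavy atoms only).

    ``fragment_ids`` labels each atom with the connected component it
    belongs to; bonded atoms must share a fragment id.
    """

    atom_elements: tuple[str, ...]
    bonds: tuple[tuple[int, int], ...]
    fragment_ids: tuple[int, ...]

    def __post_init__(self):
        n = len(self.atom_elements)
        if n == 0:
            raise InvalidInputError("ligand graph must contain at least one atom")
        if len(self.fragment_ids) != n:
            raise InvalidInputError("fragment_ids length must equal atom count")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise InvalidInputError(f"bond ({i}, {j}) out of range for {n} atoms")
            if i == j:
                raise InvalidInputError(f"self-bond on atom {i}")
            if self.fragment_ids[i] != self.fragment_ids[j]:
                raise InvalidInputError(
                    f"bonded atoms {i}, {j} carry different fragment ids"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_elements)

    @property
    def n_fragments(self) -> int:
        return len(set(self.fragment_ids))

    @property
    def fragment_labels(self) -> tuple[int, ...]:
        """Distinct fragment ids in order of first appearance."""
        seen: dict[int, None] = {}
        for f in self.fragment_ids:
            seen.setdefault(f, None)
        return tuple(seen)

    @classmethod
    def from_bonds(
        cls, atom_elements: Sequence[str], bonds: Sequence[tuple[int, int]]
    ) -> "LigandGraph":
        """Build a graph, deriving fragment ids from bond connectivity."""
        n = len(atom_elements)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in bonds:
            if 0 <= i < n and 0 <= j < n:
                parent[find(i)] = find(j)
        roots: dict[int, int] = {}
        frag = []
        for a in range(n):
            r = find(a)
            frag.append(roots.setdefault(r, len(roots)))
        return cls(
            atom_elements=tuple(atom_elements),
            bonds=tuple((int(i), int(j)) for i, j in bonds),
            fragment_ids=tuple(frag),
        )


@dataclass(frozen=True)
class ProteinStructure:
    """Protein heavy-atom structure with a residue-level Ca trace.

    ``sequence`` is a one-letter residue string of length S_P; ``ca_coords``
    is the (S_P, 3) Ca trace and ``heavy_coords`` the full (N_P, 3)
    heavy-atom set with ``atom_to_residue`` mapping every heavy atom to its
    residue. ``chain_ids`` allows multi-chain bookkeeping (one id per
    residue); chains are concatenated into a single residue list.
    """

    sequence: str
    ca_coords: np.ndarray
    heavy_coords: np.ndarray
    atom_to_residue: np.ndarray
    chain_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise InvalidInputError("protein must have at least one residue")
        object.__setattr__(
            self, "ca_coords", _as_coords(self.ca_coords, "ca_coords", len(self.sequence))
        )
        object.__setattr__(self, "heavy_coords", _as_coords(self.heavy_coords, "heavy_coords"))
        a2r = np.asarray(self.atom_to_residue, dtype=int)
        if a2r.shape != (self.heavy_coords.shape[0],):
            raise InvalidInputError("atom_to_residue must have one entry per heavy atom")
        if self.heavy_coords.shape[0] < len(self.sequence):
            raise InvalidInputError("N_P must be >= S_P")
        if a2r.size and (a2r.min() < 0 or a2r.max() >= len(self.sequence)):
            raise InvalidInputError("atom_to_residue indices out of range")
        object.__setattr__(self, "atom_to_residue", a2r)
        if not self.chain_ids:
            object.__setattr__(self, "chain_ids", ("A",) * len(self.sequence))
        elif len(self.chain_ids) != len(self.sequence):
            raise InvalidInputError("chain_ids must have one entry per residue")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_heavy_atoms(self) -> int:
        return int(self.heavy_coords.shape[0])

    def with_coords(
        self, heavy_coords: np.ndarray, ca_coords: np.ndarray | None = None
    ) -> "ProteinStructure":
        """Copy with replaced coordinates (Ca rows re-derived if omitted).

        If ``ca_coords`` is not given, Ca positions are taken from the first
        heavy atom of each residue (the bead-chain and PDB readers both
        store Ca first within a residue).
        """
        heavy = _as_coords(heavy_coords, "heavy_coords", self.n_heavy_atoms)
        if ca_coords is None:
            first = np.full(self.n_residues, -1, dtype=int)
            for a in range(heavy.shape[0] - 1, -1, -1):
                first[self.atom_to_residue[a]] = a
            ca_coords = heavy[first]
        return replace(self, heavy_coords=heavy, ca_coords=np.asarray(ca_coords, float))


@dataclass(frozen=True)
class ComplexStructure:
    """A protein-ligand complex snapshot at flow time ``t`` in [0, 1]."""

    protein: ProteinStructure
    ligand_coords: np.ndarray
    ligand_graph: LigandGraph
    t: float = 0.0

    def __post_init__(self):
        object.__setattr__(
            self,
            "ligand_coords",
            _as_coords(self.ligand_coords, "ligand_coords", self.ligand_graph.n_atoms),
        )
        if not (0.0 <= self.t <= 1.0):
            raise InvalidInputError(f"t must lie in [0, 1], got {self.t}")

    @property
    def n_atoms(self) -> int:
        return self.protein.n_heavy_atoms + self.ligand_graph.n_atoms

    def all_coords(self) -> np.ndarray:
        """Concatenated (N_P + N_L, 3) coordinates, protein first."""
        return np.vstack([self.protein.heavy_coords, self.ligand_coords])

    def ligand_mask(self) -> np.ndarray:
        """Boolean mask over ``all_coords`` rows selecting ligand atoms."""
        m = np.zeros(self.n_atoms, dtype=bool)
        m[self.protein.n_heavy_atoms :] = True
        return m

    def with_all_coords(self, coords: np.ndarray, t: float | None = None) -> "ComplexStructure":
        coords = _as_coords(coords, "coords", self.n_atoms)
        np_ = self.protein.n_heavy_atoms
        return ComplexStructure(
            protein=self.protein.with_coords(coords[:np_]),
            ligand_coords=coords[np_:],
            ligand_graph=self.ligand_graph,
            t=self.t if t is None else float(t),
        )


@dataclass(frozen=True)
class AlignmentResult:
    """Rigid superposition outcome: x_aligned = x_mobile @ rotation.T + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    tm_score: float
    degenerate: bool = False

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise InvalidInputError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise InvalidInputError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise InvalidInputError("rotation must be proper (det=+1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, float).reshape(3))
        if self.rmsd < 0:
            raise InvalidInputError("rmsd must be >= 0")
        if not (0.0 < self.tm_score <= 1.0):
            raise InvalidInputError("tm_score must lie in (0, 1]")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation
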