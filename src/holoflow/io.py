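"""File-format adapters: PDB structures, ligand graphs, manifests, configs.

Ligand inputs may be a SMILES string (parsed with RDKit when available,
multi-fragment via dot-separation), an SDF file, or the dependency-light
bond-list text format::

    # comment lines allowed
    atoms C C O
    bond 0 1
    bond 1 2

Hydrogens are stripped everywhere; only heavy atoms enter a LigandGraph.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .cfm import BatchConfig, CouplingThresholds
from .field import FieldConfig
from .solver import SolverConfig
from .structures import ComplexStructure, InvalidInputError, LigandGraph, ProteinStructure

try:  # pragma: no cover - rdkit is optional at runtime
    from rdkit import Chem

    _HAS_RDKIT = True
except Exception:  # pragma: no cover
    _HAS_RDKIT = False


class FormatError(ValueError):
    """Unparseable structure or ligand input."""


# ---------------------------------------------------------------------------
# ligand parsing


def ligand_from_smiles(smiles: str) -> LigandGraph:
    if not _HAS_RDKIT:
        raise FormatError("RDKit is unavailable; use the bond-list format instead")
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise FormatError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.RemoveHs(mol)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    return LigandGraph.from_bonds(elements, bonds)


def ligand_from_sdf(path: str) -> LigandGraph:
    if not _HAS_RDKIT:
        raise FormatError("RDKit is unavailable; use the bond-list format instead")
    supplier = Chem.SDMolSupplier(path, removeHs=True, sanitize=True)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise FormatError(f"no parseable molecule in SDF {path}")
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    return LigandGraph.from_bonds(elements, bonds)


def ligand_from_bondlist(text: str) -> LigandGraph:
    elements: list[str] = []
    bonds: list[tuple[int, int]] = []
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        tok = line.split()
        if tok[0] == "atoms":
            elements.extend(tok[1:])
        elif tok[0] == "bond":
            if len(tok) != 3:
                raise FormatError(f"line {ln}: bond needs two indices")
            bonds.append((int(tok[1]), int(tok[2])))
        else:
            raise FormatError(f"line {ln}: unknown directive {tok[0]!r}")
    if not elements:
        raise FormatError("bond-list input declares no atoms")
    elements = [e for e in elements]
    heavy = [i for i, e in enumerate(elements) if e.upper() != "H"]
    remap = {old: new for new, old in enumerate(heavy)}
    hbonds = [
        (remap[i], remap[j]) for i, j in bonds if i in remap and j in remap
    ]
    return LigandGraph.from_bonds([elements[i] for i in heavy], hbonds)


def read_ligand(source: str) -> LigandGraph:
    """Dispatch on the ligand source: SDF path, bond-list path, or SMILES string."""
    if os.path.exists(source):
        if source.endswith(".sdf"):
            return ligand_from_sdf(source)
        with open(source) as fh:
            text = fh.read()
        if "atoms" in text.split("#")[0] or any(
            l.strip().startswith(("atoms", "bond")) for l in text.splitlines()
        ):
            return ligand_from_bondlist(text)
        return ligand_from_smiles(text.strip())
    return ligand_from_smiles(source)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)


def _to_atom_array(complex_: ComplexStructure):
    import biotite.structure as struc

    prot = complex_.protein
    n_p = prot.n_heavy_atoms
    n_l = complex_.ligand_graph.n_atoms
    arr = struc.AtomArray(n_p + n_l)
    arr.coord = complex_.all_coords().astype(np.float32)

    res_seen: dict[int, int] = {}
    atom_names = []
    for a in range(n_p):
        r = int(prot.atom_to_residue[a])
        k = res_seen.get(r, 0)
        res_seen[r] = k + 1
        atom_names.append("CA" if k == 0 else "CB")
    arr.atom_name[:n_p] = atom_names
    arr.element[:n_p] = ["C"] * n_p
    arr.res_id[:n_p] = prot.atom_to_residue + 1
    arr.res_name[:n_p] = ["ALA"] * n_p
    arr.chain_id[:n_p] = [prot.chain_ids[r] for r in prot.atom_to_residue]
    arr.hetero[:n_p] = False

    arr.atom_name[n_p:] = [
        f"{e.upper()}{i+1}" for i, e in enumerate(complex_.ligand_graph.atom_elements)
    ]
    arr.element[n_p:] = [e.upper() for e in complex_.ligand_graph.atom_elements]
    arr.res_id[n_p:] = np.asarray(complex_.ligand_graph.fragment_ids) + 1
    arr.res_name[n_p:] = ["LIG"] * n_l
    arr.chain_id[n_p:] = ["L"] * n_l
    arr.hetero[n_p:] = True
    return arr


def write_complex_pdb(complex_: ComplexStructure, path: str) -> None:
    """Write protein (ATOM) + ligand (HETATM, chain L) as a single-model PDB."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile()
    pdb.set_structure(f, _to_atom_array(complex_))
    f.write(path)


def write_trajectory_pdb(
    trajectory_states: list[np.ndarray], template: ComplexStructure, path: str
) -> None:
    """Multi-model PDB (MODEL/ENDMDL) of a sampling trajectory for inspection."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    base = _to_atom_array(template)
    stack = struc.AtomArrayStack(len(trajectory_states), base.array_length())
    for cat in base.get_annotation_categories():
        stack.set_annotation(cat, base.get_annotation(cat))
    stack.coord = np.stack([s.astype(np.float32) for s in trajectory_states])
    f = pdb.PDBFile()
    pdb.set_structure(f, stack)
    f.write(path)


def read_complex_pdb(path: str) -> ComplexStructure:
    """Read a complex written by :func:`write_complex_pdb` (or any PDB whose
    ligand is stored as HETATM records; protein Ca atoms must be present)."""
    import biotite.structure.io.pdb as pdb

    arr = pdb.PDBFile.read(path).get_structure(model=1)
    prot_mask = ~arr.hetero
    lig_mask = arr.hetero
    if prot_mask.sum() == 0:
        raise FormatError(f"{path}: no protein ATOM records")

    prot = arr[prot_mask]
    # group residues by (chain, res_id) in file order
    keys = list(zip(prot.chain_id, prot.res_id))
    res_index: dict[tuple, int] = {}
    a2r = np.empty(len(keys), dtype=int)
    for i, k in enumerate(keys):
        a2r[i] = res_index.setdefault(k, len(res_index))
    n_res = len(res_index)
    ca_coords = np.zeros((n_res, 3))
    seen = set()
    for i, k in enumerate(keys):
        r = a2r[i]
        if prot.atom_name[i] == "CA" and r not in seen:
            ca_coords[r] = prot.coord[i]
            seen.add(r)
    if len(seen) != n_res:
        raise FormatError(f"{path}: some residues lack a CA atom")
    chain_of_res = [""] * n_res
    for k, r in res_index.items():
        chain_of_res[r] = str(k[0])
    protein = ProteinStructure(
        sequence="A" * n_res,
        ca_coords=ca_coords,
        heavy_coords=np.asarray(prot.coord, float),
        atom_to_residue=a2r,
        chain_ids=tuple(chain_of_res),
    )
    if lig_mask.sum():
        lig = arr[lig_mask]
        frag = {}
        frag_ids = [frag.setdefault(int(r), len(frag)) for r in lig.res_id]
        graph = LigandGraph(
            atom_elements=tuple(str(e) for e in lig.element),
            bonds=(),
            fragment_ids=tuple(frag_ids),
        )
        lig_coords = np.asarray(lig.coord, float)
    else:
        raise FormatError(f"{path}: no HETATM ligand records")
    return ComplexStructure(protein, lig_coords, graph, t=0.0)


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration hosting all printed defaults."""

    solver: SolverConfig = field(default_factory=SolverConfig)
    thresholds: CouplingThresholds = field(default_factory=CouplingThresholds)
    batch: BatchConfig = field(default_factory=BatchConfig)
    field_config: FieldConfig = field(default_factory=FieldConfig)
    seed: int = 0


_SECTIONS = {
    "solver": SolverConfig,
    "thresholds": CouplingThresholds,
    "batch": BatchConfig,
    "field_config": FieldConfig,
}


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError("config root must be a mapping")
    kwargs = {}
    for key, val in raw.items():
        if key == "seed":
            kwargs["seed"] = int(val)
        elif key in _SECTIONS:
            cls = _SECTIONS[key]
            allowed = set(cls.__dataclass_fields__)
            unknown = set(val) - allowed
            if unknown:
                raise FormatError(f"unknown keys in {key}: {sorted(unknown)}")
            kwargs[key] = cls(**val)
        else:
            raise FormatError(f"unknown config section {key!r}")
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path: str) -> None:
    data = {
        "seed": config.seed,
        **{name: asdict(getattr(config, name)) for name in _SECTIONS},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
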