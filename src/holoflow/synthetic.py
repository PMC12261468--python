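"""Synthetic apo/holo toy systems.

A "protein" is a compact self-avoiding bead chain (one Ca plus one pseudo
side-chain atom per residue, 3.8 A Ca spacing); a "ligand" is a random
small bond graph posed as a harmonic blob. The toy binding rule is
geometric: the holo ligand sits at the protein's most buried point (the
burial-weighted centroid), so the apo-to-holo transformation is learnable
from coordinates alone. Three deformation modes connect apo and holo:

- ``rigid_ligand_shift``: protein unchanged; the apo ligand is the holo
  pose rigidly translated by exactly ``deformation_scale`` Angstroms.
- ``pocket_hinge``: the C-terminal half of the chain rotates about a hinge
  through the middle residue; displacements are rescaled so the apo-holo
  Ca RMSD equals the requested scale exactly. The ligand is also shifted.
- ``global_deform``: a smooth low-frequency displacement field along the
  chain, rescaled to the exact Ca RMSD; the ligand is also shifted.

The synthetic affinity is alpha * (protein-ligand atom pairs within 4.5 A
in the holo pose) + Gaussian noise (0.3 pK), emulating a contact-driven
binding free energy on the pK scale.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np

from . import cfm, geometry
from .structures import ComplexStructure, InvalidInputError, LigandGraph, ProteinStructure

_MODES = ("rigid_ligand_shift", "pocket_hinge", "global_deform")
_AA = "ACDEFGHIKLMNPQRSTVWY"
_CONTACT_RADIUS = 4.5
_AFFINITY_NOISE_SD = 0.3


@dataclass(frozen=True)
class ToySystemSpec:
    n_residues: int = 40
    n_ligand_atoms: int = 10
    n_fragments: int = 1
    deformation_mode: str = "rigid_ligand_shift"
    deformation_scale: float = 3.0
    affinity_alpha: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 2 or self.n_ligand_atoms < 1 or self.n_fragments < 1:
            raise InvalidInputError("system sizes must be positive (>= 2 residues)")
        if self.n_fragments > self.n_ligand_atoms:
            raise InvalidInputError("more fragments than ligand atoms")
        if self.deformation_scale < 0:
            raise InvalidInputError("deformation scale must be >= 0")
        if self.deformation_mode not in _MODES:
            raise InvalidInputError(f"unknown deformation mode {self.deformation_mode!r}")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _bead_chain(n_res: int, rng: np.random.Generator) -> ProteinStructure:
    """Compact self-avoiding Ca walk with a pseudo side-chain atom per residue."""
    step = 3.8
    ca = np.zeros((n_res, 3))
    direction = _random_unit(rng)
    for i in range(1, n_res):
        for _try in range(60):
            # correlated walk, weakly biased back toward the centroid for compactness
            centroid = ca[:i].mean(axis=0)
            bias = centroid - ca[i - 1]
            norm_bias = bias / (np.linalg.norm(bias) + 1e-9)
            cand = 0.55 * direction + 0.25 * norm_bias + 0.8 * rng.standard_normal(3) / np.sqrt(3)
            cand /= np.linalg.norm(cand)
            pos = ca[i - 1] + step * cand
            if i < 2 or np.min(np.linalg.norm(ca[: i - 1] - pos, axis=1)) > 3.6:
                direction = cand
                ca[i] = pos
                break
        else:  # accept a clashing step rather than loop forever
            ca[i] = ca[i - 1] + step * direction
    ca -= ca.mean(axis=0)

    heavy = np.empty((2 * n_res, 3))
    a2r = np.empty(2 * n_res, dtype=int)
    for i in range(n_res):
        heavy[2 * i] = ca[i]  # Ca first within the residue
        heavy[2 * i + 1] = ca[i] + 1.5 * _random_unit(rng)  # pseudo side chain
        a2r[2 * i] = i
        a2r[2 * i + 1] = i
    seq = "".join(_AA[k] for k in rng.integers(0, len(_AA), n_res))
    return ProteinStructure(sequence=seq, ca_coords=ca, heavy_coords=heavy, atom_to_residue=a2r)


def _random_ligand_graph(
    n_atoms: int, n_fragments: int, rng: np.random.Generator
) -> LigandGraph:
    """Random trees (one per fragment) with an occasional ring-closing edge."""
    sizes = np.full(n_fragments, n_atoms // n_fragments)
    sizes[: n_atoms % n_fragments] += 1
    elements, bonds, frag_ids = [], [], []
    offset = 0
    for f, size in enumerate(sizes):
        for a in range(size):
            elements.append(["C", "C", "C", "N", "O"][int(rng.integers(5))])
            frag_ids.append(f)
            if a > 0:
                bonds.append((offset + int(rng.integers(a)), offset + a))
        if size >= 4 and rng.uniform() < 0.5:  # one ring closure
            i, j = rng.choice(size, size=2, replace=False)
            b = (offset + int(min(i, j)), offset + int(max(i, j)))
            if b not in bonds and b[0] != b[1]:
                bonds.append(b)
        offset += size
    return LigandGraph(tuple(elements), tuple(bonds), tuple(frag_ids))


_BOUND_COMPACTNESS = 0.5  # bound poses are compact: holo spread vs the diffuse prior


def _pose_ligand(
    graph: LigandGraph,
    center: np.ndarray,
    rng: np.random.Generator,
    spread: float = 1.0,
) -> np.ndarray:
    """Harmonic-blob pose with every fragment centred near ``center``.

    ``spread`` scales the conformational spread around the fragment
    centres; bound (holo) poses use a spread < 1 to emulate the ordered,
    compact conformations of crystal ligands relative to the diffuse
    unbound prior.
    """
    from . import priors  # local import to avoid a cycle at module load

    L = geometry.graph_laplacian(graph)
    centers = {}
    for f in set(graph.fragment_ids):
        centers[f] = center + 1.5 * rng.standard_normal(3) * (len(set(graph.fragment_ids)) > 1)
    spec = priors.HarmonicPriorSpec(L, graph.fragment_ids, centers)
    sample = priors.sample_harmonic(spec, 1, rng=rng)[0]
    if spread != 1.0:
        for f in set(graph.fragment_ids):
            m = np.asarray(graph.fragment_ids) == f
            sample[m] = centers[f] + spread * (sample[m] - centers[f])
    return sample


def _contacts(protein: ProteinStructure, ligand_coords: np.ndarray) -> int:
    d = np.linalg.norm(
        protein.heavy_coords[:, None, :] - ligand_coords[None, :, :], axis=2
    )
    return int((d < _CONTACT_RADIUS).sum())


def _scaled_protein_deform(
    protein: ProteinStructure, disp_ca: np.ndarray, scale: float
) -> ProteinStructure:
    """Apply a per-residue displacement field rescaled to an exact Ca RMSD."""
    rms = np.sqrt(np.mean(np.sum(disp_ca**2, axis=1)))
    if rms < 1e-12 or scale == 0:
        return protein
    disp = disp_ca * (scale / rms)
    heavy = protein.heavy_coords + disp[protein.atom_to_residue]
    return protein.with_coords(heavy, protein.ca_coords + disp)


def generate_system(
    spec: ToySystemSpec,
) -> tuple[ComplexStructure, ComplexStructure, float]:
    """Build one (apo, holo, true_affinity) toy system, reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    protein_holo = _bead_chain(spec.n_residues, rng)
    graph = _random_ligand_graph(spec.n_ligand_atoms, spec.n_fragments, rng)
    pocket = geometry.buried_centroid(protein_holo.heavy_coords)
    lig_holo = _pose_ligand(graph, pocket, rng, spread=_BOUND_COMPACTNESS)

    shift_dir = _random_unit(rng)
    scale = spec.deformation_scale
    if spec.deformation_mode == "rigid_ligand_shift":
        protein_apo = protein_holo
        lig_apo = lig_holo + scale * shift_dir
    else:
        if spec.deformation_mode == "pocket_hinge":
            hinge = spec.n_residues // 2
            axis = _random_unit(rng)
            angle = 0.5  # raw angle; displacements rescaled to the exact RMSD
            K = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
            )
            R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
            pivot = protein_holo.ca_coords[hinge]
            moved = (protein_holo.ca_coords - pivot) @ R.T + pivot
            disp = np.where(
                (np.arange(spec.n_residues) >= hinge)[:, None],
                moved - protein_holo.ca_coords,
                0.0,
            )
        else:  # global_deform: smooth low-frequency field along the chain
            idx = np.arange(spec.n_residues) / max(spec.n_residues - 1, 1)
            disp = np.zeros((spec.n_residues, 3))
            for k in range(1, 4):
                amp = rng.standard_normal(3) / k
                phase = rng.uniform(0, 2 * np.pi)
                disp += np.sin(np.pi * k * idx + phase)[:, None] * amp[None, :]
        protein_apo = _scaled_protein_deform(protein_holo, disp, scale)
        lig_apo = lig_holo + scale * shift_dir

    apo = ComplexStructure(protein_apo, lig_apo, graph, t=0.0)
    holo = ComplexStructure(protein_holo, lig_holo, graph, t=1.0)
    affinity = spec.affinity_alpha * _contacts(protein_holo, lig_holo) + rng.normal(
        0.0, _AFFINITY_NOISE_SD
    )
    return apo, holo, float(affinity)


# ---------------------------------------------------------------------------
# benchmark suites


def generate_benchmark_suite(
    n_systems: int,
    spec_ranges: dict | None = None,
    seed: int = 0,
    heldout_fraction: float = 0.3,
) -> list[dict]:
    """Deterministic manifest of toy systems, stratified over deformation modes.

    Training and held-out systems draw their seeds from disjoint blocks
    (``seed`` offsets 0.. and 1_000_000..), so the two splits can never
    share a system. Each manifest entry carries the fully-resolved
    ToySystemSpec and its split label.
    """
    ranges = {
        "n_residues": (30, 50),
        "n_ligand_atoms": (6, 14),
        "n_fragments": (1, 2),
        "deformation_scale": (1.0, 6.0),
        "affinity_alpha": 0.1,
        "modes": _MODES,
        **(spec_ranges or {}),
    }
    rng = np.random.default_rng(seed)
    n_heldout = int(round(n_systems * heldout_fraction))
    manifest = []
    for k in range(n_systems):
        split = "heldout" if k < n_heldout else "train"
        sys_seed = (seed % 1_000_000) + (1_000_000 + k if split == "heldout" else k)
        lo, hi = ranges["deformation_scale"]
        spec = ToySystemSpec(
            n_residues=int(rng.integers(*ranges["n_residues"])),
            n_ligand_atoms=int(rng.integers(*ranges["n_ligand_atoms"])),
            n_fragments=int(rng.integers(ranges["n_fragments"][0], ranges["n_fragments"][1] + 1)),
            deformation_mode=ranges["modes"][k % len(ranges["modes"])],
            deformation_scale=float(rng.uniform(lo, hi)),
            affinity_alpha=float(ranges["affinity_alpha"]),
            seed=sys_seed,
        )
        manifest.append({"spec": spec, "split": split})
    return manifest


def manifest_hash(manifest: list[dict]) -> str:
    """Stable content hash of a suite manifest."""
    text = "\n".join(f"{m['split']}:{m['spec']}" for m in manifest)
    return hashlib.sha256(text.encode()).hexdigest()


# ---------------------------------------------------------------------------
# calibrated similarity pairs


def _measure_pair(apo: ComplexStructure, holo: ComplexStructure) -> tuple[float, float]:
    aln = cfm.apo_holo_filter(apo, holo).alignment
    return aln.tm_score, aln.rmsd


def make_pair_with_similarity(
    tm_target: float,
    rmsd_target: float,
    n_residues: int = 100,
    seed: int = 0,
    rmsd_band: tuple[float, float] | None = None,
    tm_tol: float = 2e-3,
) -> tuple[ComplexStructure, ComplexStructure]:
    """Construct an apo/holo pair whose *measured* similarity hits a target.

    The apo protein is the holo protein displaced by a two-parameter family
    d_i = s * sigmoid(beta * (g_i - q)) * e_i (random unit directions e_i,
    fixed random profile g_i ~ U(0, 1), sharpness beta): the overall scale s
    controls the aligned RMSD while the quantile q controls the fraction of
    residues that move at all, trading RMSD against TM-score (a small
    moving fraction leaves most residues near-native, raising TM at fixed
    RMSD). Nested bisection calibrates both against the coupling filter's
    own ligand-weighted alignment, so boundary cases (e.g. RMSD exactly at
    the rejection threshold) can be placed on a chosen side via
    ``rmsd_band``.
    """
    base = ToySystemSpec(n_residues=n_residues, deformation_scale=0.0, seed=seed)
    apo0, holo, _ = generate_system(base)
    if rmsd_target == 0:
        return apo0, holo

    rng = np.random.default_rng(seed + 7)
    dirs = rng.standard_normal((n_residues, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    # movers are recruited far-from-ligand first, so the pocket (which
    # dominates the ligand-weighted alignment) deforms last — mirroring
    # pocket-conserved apo/holo pairs
    d_lig = np.linalg.norm(
        holo.protein.ca_coords[:, None, :] - holo.ligand_coords[None, :, :], axis=2
    ).min(axis=1)
    profile = np.argsort(np.argsort(d_lig)) / max(n_residues - 1, 1)
    beta = 40.0
    lo_band, hi_band = rmsd_band or (rmsd_target - 1e-9, rmsd_target + 1e-9)

    def weights(q: float) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-beta * (profile - q)))

    def deformed(s: float, q: float) -> ComplexStructure:
        disp = (s * weights(q))[:, None] * dirs
        heavy = holo.protein.heavy_coords + disp[holo.protein.atom_to_residue]
        prot = holo.protein.with_coords(heavy, holo.protein.ca_coords + disp)
        return ComplexStructure(prot, holo.ligand_coords, holo.ligand_graph, t=0.0)

    def solve_scale(q: float) -> tuple[ComplexStructure, float, float]:
        w_rms = np.sqrt(np.mean(weights(q) ** 2))
        lo, hi = 0.0, 8.0 * rmsd_target / max(w_rms, 1e-6)
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            tm, rmsd = _measure_pair(deformed(mid, q), holo)
            if lo_band <= rmsd <= hi_band:
                return deformed(mid, q), tm, rmsd
            if rmsd < rmsd_target:
                lo = mid
            else:
                hi = mid
        apo = deformed(0.5 * (lo + hi), q)
        tm, rmsd = _measure_pair(apo, holo)
        return apo, tm, rmsd

    q_lo, q_hi = 0.0, 0.995
    for _ in range(60):
        q = 0.5 * (q_lo + q_hi)
        apo, tm, rmsd = solve_scale(q)
        if abs(tm - tm_target) < tm_tol:
            return apo, holo
        if tm < tm_target:  # move fewer residues
            q_lo = q
        else:
            q_hi = q
    raise InvalidInputError(
        f"could not reach (TM={tm_target}, RMSD={rmsd_target}); best ({tm:.3f}, {rmsd:.3f})"
    )
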