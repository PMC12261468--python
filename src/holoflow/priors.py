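"""Initial-state (t=0) distributions.

Ligand coordinates are drawn from a harmonic prior: a Gaussian whose
precision matrix is the bond-graph Laplacian, so bonded atoms start close
together. The Laplacian has one zero mode (rigid translation) per fragment,
which makes the density improper; we sample only the positive-eigenvalue
modes with per-axis coefficient variance 1/lambda and pin each fragment's
centroid to a supplied center.

Protein coordinates at t=0 are a user-supplied apo structure plus i.i.d.
Gaussian noise of scale sigma per axis (default 1e-4 A during training,
off at inference).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .structures import InvalidInputError, ProteinStructure

_EIG_TOL = 1e-8  # eigenvalues below this are treated as translation null-space


@dataclass(frozen=True)
class HarmonicPriorSpec:
    """Harmonic ligand prior: precision = Laplacian, fragment centroids pinned."""

    laplacian: np.ndarray
    fragment_ids: tuple[int, ...]
    fragment_centers: dict[int, np.ndarray] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self):
        L = np.asarray(self.laplacian, float)
        n = L.shape[0]
        if L.ndim != 2 or L.shape != (n, n):
            raise InvalidInputError("laplacian must be square")
        if not np.allclose(L, L.T, atol=1e-10):
            raise InvalidInputError("laplacian must be symmetric")
        if len(self.fragment_ids) != n:
            raise InvalidInputError("fragment_ids length must match laplacian size")
        object.__setattr__(self, "laplacian", L)


@dataclass(frozen=True)
class ProteinPriorSpec:
    """Noised apo protein prior: apo coordinates + N(0, sigma) per axis."""

    apo_structure: ProteinStructure
    noise_sigma: float = 1e-4
    rng_seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise InvalidInputError("noise sigma must be >= 0")


def sample_harmonic(
    spec: HarmonicPriorSpec,
    n_samples: int = 1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ligand conformations from the harmonic prior.

    Returns an (n_samples, N_L, 3) array. Each fragment is sampled in the
    subspace orthogonal to its translation mode (coefficient variance
    1/lambda per axis for each positive eigenvalue) and then translated so
    its centroid equals the requested fragment center exactly (origin by
    default).
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    L = spec.laplacian
    n = L.shape[0]
    evals, evecs = np.linalg.eigh(L)
    if evals.min() < -1e-8:
        raise InvalidInputError("laplacian is not positive semidefinite")
    frag_ids = np.asarray(spec.fragment_ids)

    out = np.zeros((n_samples, n, 3))
    pos = evals > _EIG_TOL
    if np.any(pos):
        lam = evals[pos]
        V = evecs[:, pos]  # (n, m)
        # coefficients c ~ N(0, 1/lambda) independently per axis
        c = rng.standard_normal((n_samples, lam.size, 3)) / np.sqrt(lam)[None, :, None]
        out = np.einsum("nm,smk->snk", V, c)
    # pin each fragment centroid to its center (translation null-space)
    for f in np.unique(frag_ids):
        m = frag_ids == f
        center = np.asarray(spec.fragment_centers.get(int(f), np.zeros(3)), float)
        out[:, m, :] += center[None, None, :] - out[:, m, :].mean(axis=1, keepdims=True)
    return out


def sample_protein_prior(
    spec: ProteinPriorSpec, rng: np.random.Generator | None = None
) -> ProteinStructure:
    """Apo structure with i.i.d. Gaussian coordinate noise; sequence unchanged."""
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    apo = spec.apo_structure
    if spec.noise_sigma == 0:
        return apo
    noise = rng.normal(0.0, spec.noise_sigma, size=apo.heavy_coords.shape)
    return apo.with_coords(apo.heavy_coords + noise)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG substream derived from a single run-level seed."""
    digest = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    child = np.random.SeedSequence(seed, spawn_key=(digest,))
    return np.random.default_rng(child)
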