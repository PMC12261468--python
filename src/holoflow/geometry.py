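"""Alignment and similarity kernels: graph Laplacian, weighted Kabsch,
TM-score, and ligand-proximity residue weights.

These are the primitives the coupling filter and the priors are built on.
"""

from __future__ import annotations

import warnings

import numpy as np

from .structures import AlignmentResult, InvalidInputError, LigandGraph, ProteinStructure


class DegenerateGeometryWarning(UserWarning):
    """Point set is (near-)collinear or coincident; transform is best-effort."""


def graph_laplacian(graph: LigandGraph) -> np.ndarray:
    """Graph Laplacian L = D - A of a ligand bond graph.

    Symmetric positive-semidefinite with one zero eigenvalue per connected
    fragment; block-diagonal across fragments (under any atom ordering that
    groups fragments).
    """
    n = graph.n_atoms
    L = np.zeros((n, n), dtype=float)
    for i, j in graph.bonds:
        L[i, j] -= 1.0
        L[j, i] -= 1.0
        L[i, i] += 1.0
        L[j, j] += 1.0
    return L


def weighted_kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
    norm_length: int | None = None,
) -> AlignmentResult:
    """Weighted least-squares rigid superposition of ``mobile`` onto ``reference``.

    Minimizes sum_i w_i ||R x_i + t - y_i||^2 over proper rotations R and
    translations t (closed-form SVD solution). The reported ``rmsd`` and
    ``tm_score`` are computed over ALL points after the transform,
    unweighted, so that heavily down-weighted points still count toward the
    similarity verdict.

    Parameters
    ----------
    mobile, reference : (N, 3) arrays with N >= 3.
    weights : nonnegative per-point weights; at least 3 must be > 0.
    norm_length : TM-score normalization length (defaults to N).
    """
    X = np.asarray(mobile, float)
    Y = np.asarray(reference, float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise InvalidInputError("mobile and reference must be matching (N, 3) arrays")
    n = X.shape[0]
    if n < 3:
        raise InvalidInputError("need at least 3 points to superpose")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0):
            raise InvalidInputError("weights must be a nonnegative length-N vector")
        if np.count_nonzero(w > 0) < 3:
            raise InvalidInputError("at least 3 strictly positive weights required")
    wsum = w.sum()
    if wsum <= 0:
        raise InvalidInputError("weights must sum to a positive value")
    w = w / wsum

    mu_x = w @ X
    mu_y = w @ Y
    Xc = X - mu_x
    Yc = Y - mu_y
    H = (Xc * w[:, None]).T @ Yc  # weighted cross-covariance

    degenerate = False
    s = np.linalg.svd(H, compute_uv=False)
    if s[0] <= 0 or s[1] / max(s[0], 1e-300) < 1e-9:
        degenerate = True
        warnings.warn(
            "degenerate (collinear or coincident) point set; returning a "
            "best-effort transform",
            DegenerateGeometryWarning,
            stacklevel=2,
        )
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_y - R @ mu_x

    aligned = X @ R.T + t
    dev = np.linalg.norm(aligned - Y, axis=1)
    rmsd = float(np.sqrt(np.mean(dev**2)))
    tm = tm_score_from_deviations(dev, norm_length or n)
    return AlignmentResult(rotation=R, translation=t, rmsd=rmsd, tm_score=tm, degenerate=degenerate)


def tm_d0(norm_length: int) -> float:
    """Standard TM-score distance scale d0(L) = 1.24 (L-15)^(1/3) - 1.8, floored at 0.5 A."""
    if norm_length <= 15:
        return 0.5
    return max(0.5, 1.24 * (norm_length - 15) ** (1.0 / 3.0) - 1.8)


def tm_score_from_deviations(deviations: np.ndarray, norm_length: int) -> float:
    """TM-score sum (1/L_norm) * sum_i 1 / (1 + (d_i/d0)^2) over aligned pairs."""
    d = np.asarray(deviations, float)
    if norm_length < 1:
        raise InvalidInputError("norm_length must be >= 1")
    d0 = tm_d0(norm_length)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / norm_length)


def tm_score(
    aligned_ca_a: np.ndarray, aligned_ca_b: np.ndarray, norm_length: int | None = None
) -> float:
    """TM-score between two already-superposed Ca traces.

    Values lie in (0, 1]; exactly 1.0 iff every pairwise deviation is zero.
    No superposition is performed here — pass pre-aligned coordinates.
    """
    A = np.asarray(aligned_ca_a, float)
    B = np.asarray(aligned_ca_b, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise InvalidInputError("point sets must be matching (N, 3) arrays")
    n = A.shape[0]
    dev = np.linalg.norm(A - B, axis=1)
    return tm_score_from_deviations(dev, norm_length or n)


def tm_optimal_align(
    mobile: np.ndarray,
    reference: np.ndarray,
    norm_length: int | None = None,
    max_iter: int = 20,
) -> AlignmentResult:
    """Iterative TM-score-oriented superposition.

    Starts from an unweighted Kabsch fit, then re-fits with TM-style
    weights 1/(1 + (d_i/d0)^2) until the weights stabilize — a simple
    fixed-point surrogate for the TM-align rotation search, adequate for
    residue-matched chains.
    """
    X = np.asarray(mobile, float)
    Y = np.asarray(reference, float)
    n = X.shape[0]
    L = norm_length or n
    d0 = tm_d0(L)
    res = weighted_kabsch(X, Y, norm_length=L)
    for _ in range(max_iter):
        dev = np.linalg.norm(res.apply(X) - Y, axis=1)
        w = 1.0 / (1.0 + (dev / d0) ** 2)
        new = weighted_kabsch(X, Y, weights=w, norm_length=L)
        if abs(new.tm_score - res.tm_score) < 1e-12:
            res = new
            break
        res = new
    return res


def buried_centroid(coords: np.ndarray, sharpness: float = 2.0) -> np.ndarray:
    """Burial-weighted centroid of a point cloud — a cheap pocket proxy.

    Atoms are weighted by softmax(-sharpness * r / Rg) where r is the
    distance to the plain centroid and Rg the radius of gyration, so the
    most interior region of the cloud dominates. Used both as the toy
    binding-site rule of the synthetic systems and as a geometric feature
    the endpoint field can point at.
    """
    X = np.asarray(coords, float)
    c = X.mean(axis=0)
    r = np.linalg.norm(X - c, axis=1)
    rg = np.sqrt(np.mean(r**2))
    if rg < 1e-9:
        return c
    w = np.exp(-sharpness * r / rg)
    w /= w.sum()
    return w @ X


def ligand_proximity_weights(
    protein: ProteinStructure, ligand_coords: np.ndarray, scale: float = 4.0
) -> np.ndarray:
    """Per-residue alignment weights concentrated on the binding pocket.

    w_i proportional to exp(-d_i / scale) with d_i the minimum distance from
    residue i's Ca to any ligand heavy atom; normalized to sum to 1. The
    exponential decay focuses a superposition fit on pocket residues while
    every residue keeps a strictly positive weight.
    """
    lig = np.asarray(ligand_coords, float)
    if lig.ndim != 2 or lig.shape[1] != 3 or lig.shape[0] == 0:
        raise InvalidInputError("ligand_coords must be a nonempty (N, 3) array")
    if scale <= 0:
        raise InvalidInputError("scale must be positive")
    d = np.linalg.norm(protein.ca_coords[:, None, :] - lig[None, :, :], axis=2).min(axis=1)
    w = np.exp(-d / scale)
    return w / w.sum()
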