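"""Conditional flow-matching machinery.

Training pairs a prior draw (noised apo protein, harmonic ligand) with a
holo complex along the CondOT path x_t = (1-t) x0 + t x1, and regresses an
endpoint predictor v(x_t, t) ~ x1 under a mean-squared loss. The coupling
between prior and data is *unbalanced*: apo/holo pairs whose protein
structures are too dissimilar — TM-score below c_TM or aligned RMSD at or
above c_RMSD — are rejected before they can enter a training batch.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from . import geometry, priors
from .structures import AlignmentResult, ComplexStructure, InvalidInputError


class RejectReason(enum.Enum):
    NONE = "none"
    TM_BELOW = "tm_below"
    RMSD_ABOVE = "rmsd_above"
    LENGTH = "length"


@dataclass(frozen=True)
class CouplingThresholds:
    """Apo-holo acceptance filters (c_A).

    A pair is accepted iff TM >= tm_min AND rmsd < rmsd_max (strict, so a
    pair sitting exactly at the RMSD bound is rejected) and the residue /
    ligand-atom counts fall inside the configured bounds.
    """

    tm_min: float = 0.7
    rmsd_max: float = 5.0
    min_residues: int = 10
    max_residues: int = 2000
    min_ligand_atoms: int = 1
    max_ligand_atoms: int = 200

    def __post_init__(self):
        if not (0.0 < self.tm_min <= 1.0):
            raise InvalidInputError("tm_min must lie in (0, 1]")
        if self.rmsd_max <= 0:
            raise InvalidInputError("rmsd_max must be positive")


@dataclass(frozen=True)
class CouplingDecision:
    alignment: AlignmentResult
    accepted: bool
    reject_reason: RejectReason

    def __post_init__(self):
        if self.accepted != (self.reject_reason is RejectReason.NONE):
            raise InvalidInputError("accepted must match reject_reason == NONE")


@dataclass(frozen=True)
class PathSample:
    """One training tuple along the CondOT path; target is the endpoint x1."""

    x0: np.ndarray
    x1: np.ndarray
    t: float
    xt: np.ndarray
    target: np.ndarray
    ligand_mask: np.ndarray
    fragment_ids: tuple[int, ...] = ()
    pair_index: int = 0


def condot_interpolate(x0: np.ndarray, x1: np.ndarray, t: float) -> np.ndarray:
    """Linear (CondOT) interpolation x_t = (1-t) x0 + t x1."""
    x0 = np.asarray(x0, float)
    x1 = np.asarray(x1, float)
    if x0.shape != x1.shape:
        raise InvalidInputError(f"shape mismatch: {x0.shape} vs {x1.shape}")
    if not (0.0 <= t <= 1.0):
        raise InvalidInputError(f"t must lie in [0, 1], got {t}")
    return (1.0 - t) * x0 + t * x1


def cfm_endpoint_loss(
    predicted: np.ndarray, x1: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Endpoint regression loss: mean over (unmasked) atoms of ||v - x1||^2.

    The squared Euclidean deviation is summed over the three coordinates of
    each atom and averaged over atoms, so a uniform 1 A offset on every
    atom yields exactly 1.0. Frame-dependent by design: translating both
    arguments together leaves the loss unchanged, translating one does not.
    """
    p = np.asarray(predicted, float)
    y = np.asarray(x1, float)
    if p.shape != y.shape:
        raise InvalidInputError(f"shape mismatch: {p.shape} vs {y.shape}")
    sq = np.sum((p - y) ** 2, axis=-1)
    if mask is not None:
        m = np.asarray(mask, bool)
        if m.shape != sq.shape:
            raise InvalidInputError("mask shape must match the atom dimension")
        if not m.any():
            raise InvalidInputError("mask selects no atoms")
        sq = sq[m]
    return float(np.mean(sq))


def apo_holo_filter(
    apo: ComplexStructure,
    holo: ComplexStructure,
    thresholds: CouplingThresholds = CouplingThresholds(),
    tm_optimal: bool = False,
) -> CouplingDecision:
    """Decide whether an apo/holo pair may enter the training coupling.

    The apo Ca trace is superposed onto the holo Ca trace with
    ligand-proximity weights (pocket-focused fit against the crystal
    ligand); TM-score and RMSD are then measured over all residues. With
    ``tm_optimal`` the superposition instead iterates toward the
    TM-score-optimal rotation.
    """
    if apo.protein.n_residues != holo.protein.n_residues:
        raise InvalidInputError(
            "apo and holo proteins must be residue-matched "
            f"({apo.protein.n_residues} vs {holo.protein.n_residues})"
        )
    n_res = holo.protein.n_residues
    norm_len = n_res

    if tm_optimal:
        aln = geometry.tm_optimal_align(
            apo.protein.ca_coords, holo.protein.ca_coords, norm_length=norm_len
        )
    else:
        w = geometry.ligand_proximity_weights(holo.protein, holo.ligand_coords)
        aln = geometry.weighted_kabsch(
            apo.protein.ca_coords, holo.protein.ca_coords, weights=w, norm_length=norm_len
        )

    if not (thresholds.min_residues <= n_res <= thresholds.max_residues) or not (
        thresholds.min_ligand_atoms
        <= holo.ligand_graph.n_atoms
        <= thresholds.max_ligand_atoms
    ):
        return CouplingDecision(aln, False, RejectReason.LENGTH)
    if aln.tm_score < thresholds.tm_min:
        return CouplingDecision(aln, False, RejectReason.TM_BELOW)
    if aln.rmsd >= thresholds.rmsd_max:
        return CouplingDecision(aln, False, RejectReason.RMSD_ABOVE)
    return CouplingDecision(aln, True, RejectReason.NONE)


@dataclass(frozen=True)
class BatchConfig:
    """How prior draws are built when assembling training batches."""

    noise_sigma: float = 1e-4
    ligand_prior: str = "harmonic"  # "harmonic" | "apo"
    center_mode: str = "protein_centroid"  # "protein_centroid" | "apo_ligand" | "origin"


def _prior_center(pair_apo: ComplexStructure, mode: str) -> np.ndarray:
    if mode == "protein_centroid":
        return pair_apo.protein.heavy_coords.mean(axis=0)
    if mode == "apo_ligand":
        return pair_apo.ligand_coords.mean(axis=0)
    if mode == "origin":
        return np.zeros(3)
    raise InvalidInputError(f"unknown center mode {mode!r}")


def build_prior_draw(
    apo: ComplexStructure,
    rng: np.random.Generator,
    config: BatchConfig = BatchConfig(),
) -> np.ndarray:
    """One x0 draw: noised apo protein atoms + harmonic (or apo) ligand atoms."""
    prot = priors.sample_protein_prior(
        priors.ProteinPriorSpec(apo.protein, noise_sigma=config.noise_sigma), rng=rng
    )
    if config.ligand_prior == "harmonic":
        L = geometry.graph_laplacian(apo.ligand_graph)
        center = _prior_center(apo, config.center_mode)
        spec = priors.HarmonicPriorSpec(
            laplacian=L,
            fragment_ids=apo.ligand_graph.fragment_ids,
            fragment_centers={f: center for f in set(apo.ligand_graph.fragment_ids)},
        )
        lig = priors.sample_harmonic(spec, 1, rng=rng)[0]
    elif config.ligand_prior == "apo":
        lig = apo.ligand_coords
    else:
        raise InvalidInputError(f"unknown ligand prior {config.ligand_prior!r}")
    return np.vstack([prot.heavy_coords, lig])


def sample_training_batch(
    pairs: list[tuple[ComplexStructure, ComplexStructure]],
    batch_size: int,
    seed: int,
    config: BatchConfig = BatchConfig(),
) -> list[PathSample]:
    """Draw a batch of CondOT path samples from accepted apo/holo pairs.

    Each sample picks a pair uniformly, draws x0 from the prior (harmonic
    ligand, noised apo protein), noises the holo endpoint coordinates with
    sigma, samples t ~ U(0, 1) and interpolates. ``target`` is always the
    (noised) endpoint x1.
    """
    if not pairs:
        raise InvalidInputError(
            "empty pair pool: no apo/holo pairs survived the coupling filter "
            "(thresholds may be too strict)"
        )
    rng = np.random.default_rng(seed)
    out: list[PathSample] = []
    for _ in range(batch_size):
        k = int(rng.integers(len(pairs)))
        apo, holo = pairs[k]
        x0 = build_prior_draw(apo, rng, config)
        x1 = holo.all_coords() + rng.normal(0.0, config.noise_sigma, (holo.n_atoms, 3))
        t = float(rng.uniform())
        xt = condot_interpolate(x0, x1, t)
        out.append(
            PathSample(
                x0=x0, x1=x1, t=t, xt=xt, target=x1,
                ligand_mask=holo.ligand_mask(),
                fragment_ids=holo.ligand_graph.fragment_ids,
                pair_index=k,
            )
        )
    return out
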