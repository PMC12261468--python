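"""Confidence and affinity scoring heads, plus sample ranking and metrics.

Both heads are small ridge regressions over rigid-motion-invariant
interface descriptors of a complex (contact counts at several radii,
clash counts, interface distances, ligand compactness, bond-length
strain). The confidence head is trained against a structural quality
signal (negative ligand RMSD to the truth on synthetic systems); the
affinity head against pK-scale binding affinities (-log10 molar), the
PDBBind-style convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Ridge

from .structures import ComplexStructure, InvalidInputError

_CONTACT_RADII = (2.5, 3.5, 4.5, 6.0)
_CLASH_RADIUS = 2.0


def interface_descriptors(complex_: ComplexStructure) -> np.ndarray:
    """Rigid-motion-invariant descriptor vector of a protein-ligand pose."""
    prot = complex_.protein.heavy_coords
    lig = complex_.ligand_coords
    d = np.linalg.norm(prot[:, None, :] - lig[None, :, :], axis=2)
    per_lig_min = d.min(axis=0)
    n_l = lig.shape[0]

    feats = [d[d < r].size / n_l for r in _CONTACT_RADII]  # contacts per ligand atom
    feats.append(d[d < _CLASH_RADIUS].size / n_l)  # clashes
    feats.append(float(per_lig_min.mean()))
    feats.append(float(per_lig_min.min()))
    c_l = lig.mean(axis=0)
    feats.append(float(np.sqrt(np.mean(np.sum((lig - c_l) ** 2, axis=1)))))  # ligand Rg
    if complex_.ligand_graph.bonds:
        bl = [
            np.linalg.norm(lig[i] - lig[j])
            for i, j in complex_.ligand_graph.bonds
        ]
        feats.append(float(np.mean(bl)))
        feats.append(float(np.var(bl)))
    else:
        feats.extend([0.0, 0.0])
    return np.asarray(feats)


class _DescriptorRidge(BaseEstimator, RegressorMixin):
    """Ridge regression over interface descriptors of complexes."""

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def _design(self, complexes) -> np.ndarray:
        X = np.stack([interface_descriptors(c) for c in complexes])
        return X

    def fit(self, complexes, y):
        y = np.asarray(y, float)
        if len(complexes) != y.shape[0]:
            raise InvalidInputError("one target per complex required")
        X = self._design(complexes)
        self.x_mean_ = X.mean(axis=0)
        self.x_scale_ = X.std(axis=0)
        self.x_scale_[self.x_scale_ < 1e-12] = 1.0
        self.model_ = Ridge(alpha=self.alpha)
        self.model_.fit((X - self.x_mean_) / self.x_scale_, y)
        return self

    def predict(self, complexes) -> np.ndarray:
        X = self._design(complexes)
        return self.model_.predict((X - self.x_mean_) / self.x_scale_)

    def predict_one(self, complex_: ComplexStructure) -> float:
        return float(self.predict([complex_])[0])


class ConfidenceHead(_DescriptorRidge):
    """Scores pose quality; train against e.g. negative ligand RMSD to truth."""


class AffinityHead(_DescriptorRidge):
    """Predicts binding affinity on the pK (-log10 molar) scale."""


@dataclass(frozen=True)
class RankedPrediction:
    """A generated holo structure with its ranking scalars."""

    structure: ComplexStructure
    confidence: float
    affinity: float
    rank: int = 0
    sample_index: int = 0


def rank_samples(
    predictions: list[RankedPrediction], key: str = "confidence"
) -> list[RankedPrediction]:
    """Stable descending sort by ``key`` ('confidence' or 'affinity').

    Ties are broken by sample index (input order), so all-equal scores
    preserve the input ordering; returned ranks are the permutation 1..n.
    """
    if not predictions:
        raise InvalidInputError("cannot rank an empty prediction list")
    if key not in ("confidence", "affinity"):
        raise InvalidInputError(f"unknown ranking key {key!r}")
    order = sorted(
        range(len(predictions)), key=lambda i: -getattr(predictions[i], key)
    )  # sorted() is stable: ties keep input order
    out = []
    for rank, i in enumerate(order, start=1):
        p = predictions[i]
        out.append(
            RankedPrediction(
                structure=p.structure,
                confidence=p.confidence,
                affinity=p.affinity,
                rank=rank,
                sample_index=i,
            )
        )
    return out


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    """Pearson, Spearman, RMSE and MAE of an affinity (or any) regression."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 2:
        raise InvalidInputError("need two equal-length 1-D arrays of size >= 2")
    return {
        "pearson": float(stats.pearsonr(y_true, y_pred).statistic),
        "spearman": float(stats.spearmanr(y_true, y_pred).statistic),
        "rmse": float(np.sqrt(np.mean((y_true - y_pred) ** 2))),
        "mae": float(np.mean(np.abs(y_true - y_pred))),
    }
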