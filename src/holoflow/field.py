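"""Toy trainable endpoint field over protein+ligand point clouds.

The field stands in for a full neural vector-field backbone: it is a
one-pass equivariant message model whose per-atom update is a learned
linear combination of geometric direction channels (differences of atom
positions, molecule centroids, a burial-weighted pocket proxy, and
radial-basis-weighted neighbour messages across the protein/ligand
interface), each modulated by a polynomial time embedding. Because the
trainable weights enter linearly, training with the CondOT endpoint loss
is a well-conditioned least-squares problem optimized here with Adam so a
training curve exists.

Rigid-motion behaviour: every channel is a difference of positions, so the
predicted update is translation-invariant and rotation-equivariant; the
predicted endpoint x_t + update transforms with the frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import geometry
from .cfm import PathSample, cfm_endpoint_loss
from .structures import InvalidInputError


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during field training."""


def _time_basis(t: float, dim: int) -> np.ndarray:
    # polynomial embedding [1, t, t^2, ...]; dim >= 2 lets weights shrink as t -> 1
    return np.power(t, np.arange(dim))


def _rbf_centers(cutoff: float, k: int) -> np.ndarray:
    return np.linspace(0.5, cutoff, k)


class EndpointField(BaseEstimator, RegressorMixin):
    """Equivariant endpoint predictor v(x_t, t) -> x1 (sklearn-style).

    Parameters
    ----------
    hidden_width : number of radial basis functions per message layer.
    n_layers : message layers; layer l uses cutoff ``neighbor_cutoff * l``
        so deeper configurations see longer-range context.
    neighbor_cutoff : base interface message cutoff in Angstroms.
    time_embedding_dim : polynomial time-embedding size.
    learning_rate : Adam step size.
    weight_decay : L2 penalty on the channel weights; the geometric
        channels are partially collinear, and the penalty keeps the fit at
        the minimum-norm solution so off-distribution extrapolation stays
        tame.
    seed : reproducibility seed for minibatch order.

    Fitted attributes
    -----------------
    coef_ : learned channel weights, shape (2, n_channels, time_dim)
        (index 0 = protein atoms, 1 = ligand atoms).
    loss_history_ : per-step training loss.
    init_loss_ : loss at initialization (all-zero weights).
    """

    _N_GLOBAL = 4  # pocket-centroid shift, ligand contraction, pocket pull, core pull

    def __init__(
        self,
        hidden_width: int = 6,
        n_layers: int = 1,
        neighbor_cutoff: float = 10.0,
        time_embedding_dim: int = 5,
        learning_rate: float = 0.05,
        weight_decay: float = 1e-3,
        seed: int = 0,
    ):
        self.hidden_width = hidden_width
        self.n_layers = n_layers
        self.neighbor_cutoff = neighbor_cutoff
        self.time_embedding_dim = time_embedding_dim
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.seed = seed

    # ---- feature construction -------------------------------------------------

    @property
    def _n_channels(self) -> int:
        return self._N_GLOBAL + self.hidden_width * self.n_layers

    def _features(
        self,
        coords: np.ndarray,
        ligand_mask: np.ndarray,
        fragment_ids: tuple[int, ...] | None = None,
    ) -> np.ndarray:
        """Per-atom direction channels, shape (N, C, 3).

        Ligand centroids are taken per fragment, so multi-fragment ligands
        are each contracted/translated about their own centre.
        """
        x = np.asarray(coords, float)
        m = np.asarray(ligand_mask, bool)
        n = x.shape[0]
        prot = x[~m]
        lig = x[m]
        if prot.shape[0] == 0 or lig.shape[0] == 0:
            raise InvalidInputError("field needs both protein and ligand atoms")
        c_p = prot.mean(axis=0)
        pocket = geometry.buried_centroid(prot)

        frags = np.zeros(lig.shape[0], dtype=int)
        if fragment_ids is not None and len(fragment_ids) == lig.shape[0]:
            frags = np.asarray(fragment_ids, int)
        c_frag = np.empty_like(lig)
        for f in np.unique(frags):
            sel = frags == f
            c_frag[sel] = lig[sel].mean(axis=0)

        F = np.zeros((n, self._n_channels, 3))
        # channel 0: rigid pull of each fragment's centroid toward the pocket
        F[m, 0] = pocket - c_frag
        F[~m, 0] = 0.0
        # channel 1: contraction toward own (fragment) centroid
        F[m, 1] = c_frag - lig
        F[~m, 1] = c_p - prot
        # channel 2: per-atom pull toward the pocket proxy
        F[m, 2] = pocket - lig
        # channel 3: pull toward the protein core
        F[m, 3] = c_p - lig
        F[~m, 3] = 0.0

        # interface messages: RBF-weighted unit vectors to the other molecule
        d = np.linalg.norm(x[m][:, None, :] - prot[None, :, :], axis=2)
        vec = prot[None, :, :] - x[m][:, None, :]
        unit = vec / (d[:, :, None] + 1.0)
        d_lp = np.linalg.norm(prot[:, None, :] - lig[None, :, :], axis=2)
        vec_p = lig[None, :, :] - prot[:, None, :]
        unit_p = vec_p / (d_lp[:, :, None] + 1.0)
        ch = self._N_GLOBAL
        for layer in range(1, self.n_layers + 1):
            cutoff = self.neighbor_cutoff * layer
            centers = _rbf_centers(cutoff, self.hidden_width)
            gamma = (cutoff / self.hidden_width) ** 2
            for k, mu in enumerate(centers):
                wl = np.exp(-((d - mu) ** 2) / (2 * gamma)) * (d < cutoff)
                F[m, ch] = np.einsum("ab,abk->ak", wl, unit) / prot.shape[0]
                wp = np.exp(-((d_lp - mu) ** 2) / (2 * gamma)) * (d_lp < cutoff)
                F[~m, ch] = np.einsum("ab,abk->ak", wp, unit_p) / lig.shape[0]
                ch += 1
        return F

    def _predict_from_features(
        self, coords: np.ndarray, F: np.ndarray, ligand_mask: np.ndarray, t: float
    ) -> np.ndarray:
        tau = _time_basis(t, self.time_embedding_dim)
        w = self.coef_ @ tau  # (2, C)
        type_idx = np.asarray(ligand_mask, bool).astype(int)
        per_atom_w = w[type_idx]  # (N, C)
        return np.asarray(coords, float) + np.einsum("nc,nck->nk", per_atom_w, F)

    # ---- sklearn-style API ----------------------------------------------------

    def predict(
        self,
        coords: np.ndarray,
        t: float,
        ligand_mask: np.ndarray,
        fragment_ids: tuple[int, ...] | None = None,
    ) -> np.ndarray:
        """Endpoint (holo) estimate for a complex state at flow time t."""
        if not hasattr(self, "coef_"):
            # unfitted field = identity endpoint (zero update); keeps the
            # 0-training-steps contract usable
            self.coef_ = np.zeros((2, self._n_channels, self.time_embedding_dim))
        F = self._features(coords, ligand_mask, fragment_ids)
        return self._predict_from_features(coords, F, ligand_mask, float(t))

    def as_field(self, ligand_mask: np.ndarray, fragment_ids: tuple[int, ...] | None = None):
        """Closure with the (coords, t) -> coords signature the solvers expect."""
        mask = np.asarray(ligand_mask, bool)
        return lambda coords, t: self.predict(coords, t, mask, fragment_ids)

    def fit(self, samples, steps: int = 2000):
        """Train on CondOT path samples with Adam on the endpoint loss.

        ``samples`` is a list of PathSample or a callable step -> list of
        PathSample (a fresh-batch source). With ``steps=0`` the field stays
        at initialization but is still usable.
        """
        rng = np.random.default_rng(self.seed)
        get_batch = samples if callable(samples) else (lambda _s: samples)

        first = get_batch(0)
        if not first:
            raise InvalidInputError("empty training batch")

        def prep(s):
            return (
                s.xt,
                self._features(s.xt, s.ligand_mask, s.fragment_ids),
                np.asarray(s.ligand_mask, bool).astype(int),
                s.target,
                _time_basis(s.t, self.time_embedding_dim),
            )

        # a fixed sample list is featurized once; fresh-batch sources are
        # featurized per step
        fixed_prepared = None if callable(samples) else [prep(s) for s in samples]

        def prepared(batch):
            if fixed_prepared is not None:
                return fixed_prepared
            return [prep(s) for s in batch]

        C, T = self._n_channels, self.time_embedding_dim
        w = np.zeros((2, C, T))
        mom = np.zeros_like(w)
        vel = np.zeros_like(w)
        b1, b2, eps = 0.9, 0.999, 1e-8

        def batch_loss_and_grad(items, weights):
            loss = 0.0
            grad = np.zeros_like(weights)
            for xt, F, types, y, tau in items:
                per_w = (weights @ tau)[types]  # (N, C)
                pred = xt + np.einsum("nc,nck->nk", per_w, F)
                r = pred - y  # (N, 3)
                loss += float(np.mean(np.sum(r**2, axis=1)))
                # d loss / d w[type, c, j] = (2/N) sum_a (r_a . F_a_c) tau_j
                rF = np.einsum("nk,nck->nc", r, F) * (2.0 / xt.shape[0])
                for ty in (0, 1):
                    sel = types == ty
                    if sel.any():
                        grad[ty] += np.outer(rF[sel].sum(axis=0), tau)
            return loss / len(items), grad / len(items)

        self.init_loss_, _ = batch_loss_and_grad(prepared(first), w)
        self.loss_history_ = []
        for step in range(int(steps)):
            batch = prepared(get_batch(step))
            loss, grad = batch_loss_and_grad(batch, w)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"loss became non-finite at step {step}")
            mom = b1 * mom + (1 - b1) * grad
            vel = b2 * vel + (1 - b2) * grad**2
            mhat = mom / (1 - b1 ** (step + 1))
            vhat = vel / (1 - b2 ** (step + 1))
            w = w - self.learning_rate * (
                mhat / (np.sqrt(vhat) + eps) + self.weight_decay * w
            )
            self.loss_history_.append(loss)
        self.coef_ = w
        return self

    def score_batch(self, samples: list[PathSample]) -> float:
        """Mean endpoint loss of the current field over path samples."""
        losses = [
            cfm_endpoint_loss(self.predict(s.xt, s.t, s.ligand_mask, s.fragment_ids), s.target)
            for s in samples
        ]
        return float(np.mean(losses))


@dataclass(frozen=True)
class FieldConfig:
    """Bag of field hyperparameters mirrored into EndpointField."""

    hidden_width: int = 6
    n_layers: int = 1
    neighbor_cutoff: float = 10.0
    time_embedding_dim: int = 5
    seed: int = 0

    def __post_init__(self):
        if min(self.hidden_width, self.n_layers, self.time_embedding_dim) < 1:
            raise InvalidInputError("field sizes must be positive")
        if self.neighbor_cutoff <= 0:
            raise InvalidInputError("neighbor cutoff must be positive")


def train_field(batches, config: FieldConfig = FieldConfig(), steps: int = 2000) -> EndpointField:
    """Convenience wrapper: build an EndpointField from a config and fit it."""
    f = EndpointField(
        hidden_width=config.hidden_width,
        n_layers=config.n_layers,
        neighbor_cutoff=config.neighbor_cutoff,
        time_embedding_dim=config.time_embedding_dim,
        seed=config.seed,
    )
    return f.fit(batches, steps=steps)
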