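"""End-to-end desk-scale pipeline: filter pairs, train the toy field,
sample holo structures with the VD-ODE, and rank them with the heads."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cfm, heads, solver, synthetic
from .field import EndpointField, FieldConfig, train_field
from .structures import ComplexStructure


def ligand_rmsd(pred_ligand: np.ndarray, true_ligand: np.ndarray) -> float:
    """Plain (in-frame) RMSD between predicted and true ligand coordinates."""
    diff = np.asarray(pred_ligand, float) - np.asarray(true_ligand, float)
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def filter_pairs(
    systems: list[tuple[ComplexStructure, ComplexStructure]],
    thresholds: cfm.CouplingThresholds = cfm.CouplingThresholds(),
) -> tuple[list[tuple[ComplexStructure, ComplexStructure]], list[cfm.CouplingDecision]]:
    """Apply the unbalanced-coupling filter; return accepted pairs + all decisions."""
    decisions = [cfm.apo_holo_filter(a, h, thresholds) for a, h in systems]
    accepted = [p for p, d in zip(systems, decisions) if d.accepted]
    return accepted, decisions


@dataclass
class TrainedPipeline:
    """A trained toy field plus fitted scoring heads and their configs."""

    field: EndpointField
    confidence_head: heads.ConfidenceHead
    affinity_head: heads.AffinityHead
    solver_config: solver.SolverConfig
    batch_config: cfm.BatchConfig


def dock(
    apo: ComplexStructure,
    pipeline: TrainedPipeline,
    n_samples: int = 5,
    seed: int = 0,
) -> list[heads.RankedPrediction]:
    """Sample ``n_samples`` holo candidates from the prior and rank them.

    Each candidate draws its own prior state (noised apo protein, harmonic
    ligand centred per the batch config), integrates the VD-ODE with the
    trained endpoint field, then receives confidence and affinity scores.
    """
    rng = np.random.default_rng(seed)
    mask = apo.ligand_mask()
    field_fn = pipeline.field.as_field(mask, apo.ligand_graph.fragment_ids)
    preds = []
    for k in range(n_samples):
        x0 = cfm.build_prior_draw(apo, rng, pipeline.batch_config)
        traj = solver.integrate(x0, field_fn, pipeline.solver_config)
        structure = apo.with_all_coords(traj.final, t=1.0)
        preds.append(
            heads.RankedPrediction(
                structure=structure,
                confidence=pipeline.confidence_head.predict_one(structure),
                affinity=pipeline.affinity_head.predict_one(structure),
                sample_index=k,
            )
        )
    return heads.rank_samples(preds, key="confidence")


def train_on_suite(
    manifest: list[dict],
    field_config: FieldConfig = FieldConfig(),
    steps: int = 2000,
    batch_size: int = 24,
    seed: int = 0,
    thresholds: cfm.CouplingThresholds = cfm.CouplingThresholds(),
    batch_config: cfm.BatchConfig = cfm.BatchConfig(),
    solver_config: solver.SolverConfig = solver.SolverConfig(),
) -> tuple[TrainedPipeline, dict]:
    """Train field + heads on a suite manifest's training split.

    Returns the trained pipeline and a report with the realized systems,
    training curve, and the accepted-pair decisions.
    """
    realized = {
        split: [
            (synthetic.generate_system(m["spec"]), m["spec"])
            for m in manifest
            if m["split"] == split
        ]
        for split in ("train", "heldout")
    }
    train_pairs_all = [(apo, holo) for (apo, holo, _), _ in realized["train"]]
    accepted, decisions = filter_pairs(train_pairs_all, thresholds)

    def batch_source(step: int):
        return cfm.sample_training_batch(
            accepted, batch_size, seed=seed * 100_003 + step, config=batch_config
        )

    fld = train_field(batch_source, field_config, steps=steps)

    # fit heads on perturbed training poses labelled with their true quality
    rng = np.random.default_rng(seed + 31)
    structures, quality, affinities = [], [], []
    for (apo, holo, pk), _spec in realized["train"]:
        for sigma in (0.0, 1.0, 3.0):
            lig = holo.ligand_coords + rng.normal(0.0, sigma, holo.ligand_coords.shape)
            s = ComplexStructure(holo.protein, lig, holo.ligand_graph, t=1.0)
            structures.append(s)
            quality.append(-ligand_rmsd(lig, holo.ligand_coords))
            affinities.append(pk)
    conf = heads.ConfidenceHead().fit(structures, quality)
    aff = heads.AffinityHead().fit(
        [ComplexStructure(h.protein, h.ligand_coords, h.ligand_graph, t=1.0)
         for (a, h, _), _ in realized["train"]],
        [pk for (_, _, pk), _ in realized["train"]],
    )
    pipe = TrainedPipeline(fld, conf, aff, solver_config, batch_config)
    report = {
        "realized": realized,
        "decisions": decisions,
        "n_accepted": len(accepted),
        "init_loss": fld.init_loss_,
        "final_loss": fld.loss_history_[-1] if fld.loss_history_ else fld.init_loss_,
    }
    return pipe, report


def evaluate_transport(
    pipeline: TrainedPipeline,
    heldout: list[tuple[tuple[ComplexStructure, ComplexStructure, float], object]],
    seed: int = 0,
) -> dict:
    """Prior-vs-posterior ligand RMSD on held-out systems.

    For each held-out system one prior state is drawn and integrated; the
    report compares the ligand RMSD to truth of the prior draw against the
    VD-ODE final state.
    """
    rng = np.random.default_rng(seed)
    prior_rmsds, final_rmsds = [], []
    for (apo, holo, _pk), _spec in heldout:
        mask = apo.ligand_mask()
        x0 = cfm.build_prior_draw(apo, rng, pipeline.batch_config)
        n_p = apo.protein.n_heavy_atoms
        prior_rmsds.append(ligand_rmsd(x0[n_p:], holo.ligand_coords))
        field_fn = pipeline.field.as_field(mask, apo.ligand_graph.fragment_ids)
        traj = solver.integrate(x0, field_fn, pipeline.solver_config)
        final_rmsds.append(ligand_rmsd(traj.final[n_p:], holo.ligand_coords))
    return {
        "prior_median_rmsd": float(np.median(prior_rmsds)),
        "final_median_rmsd": float(np.median(final_rmsds)),
        "prior_rmsds": prior_rmsds,
        "final_rmsds": final_rmsds,
    }
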