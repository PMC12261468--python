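import numpy as np
import pytest

from holoflow import cfm, pipeline, synthetic


@pytest.fixture(scope="session")
def rigid_suite():
    """50 rigid-ligand-shift systems: the transport benchmark world."""
    return synthetic.generate_benchmark_suite(
        50, spec_ranges={"modes": ("rigid_ligand_shift",)}, seed=11
    )


@pytest.fixture(scope="session")
def trained_pipeline(rigid_suite):
    """Pipeline trained once per session (1500 steps, ~15 s)."""
    pipe, report = pipeline.train_on_suite(
        rigid_suite, steps=1500, batch_size=32, seed=11
    )
    return pipe, report


@pytest.fixture(scope="session")
def affinity_world():
    """80 mixed-mode systems with a fitted affinity head (train/held-out)."""
    from holoflow.heads import AffinityHead

    manifest = synthetic.generate_benchmark_suite(80, seed=21)
    realized = {
        split: [synthetic.generate_system(m["spec"]) for m in manifest if m["split"] == split]
        for split in ("train", "heldout")
    }
    head = AffinityHead().fit(
        [h for _, h, _ in realized["train"]], [pk for _, _, pk in realized["train"]]
    )
    return head, realized


@pytest.fixture()
def small_system():
    spec = synthetic.ToySystemSpec(
        n_residues=20, n_ligand_atoms=6, deformation_scale=2.0, seed=5
    )
    return synthetic.generate_system(spec)


@pytest.fixture()
def small_pair_pool():
    pool = []
    for seed in range(4):
        spec = synthetic.ToySystemSpec(
            n_residues=15, n_ligand_atoms=5, deformation_scale=1.0, seed=seed
        )
        apo, holo, _ = synthetic.generate_system(spec)
        pool.append((apo, holo))
    return pool
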