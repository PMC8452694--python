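import numpy as np
import pytest

import hsifuse as hf
from hsifuse.io import HSICube, unfold
from hsifuse.multiset import assemble, balance
from hsifuse.phantom import PhantomSpec, generate_phantom
from hsifuse.pipeline import RunConfig, run_pipeline
from hsifuse.preprocessing import PreprocessPlan


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cube(rng):
    """A 4 x 5 x 7 random cube with full validity."""
    return HSICube(
        data=rng.random((4, 5, 7)),
        axis=np.linspace(400.0, 700.0, 7),
        pixel_size=2.0,
        modality="fluorescence",
        sample_id="s1",
        axis_unit="nm",
    )


@pytest.fixture(scope="session")
def clean_phantom():
    """Congruent-grid, artifact-free 3-sample x 3-platform phantom (K=4)."""
    return generate_phantom(PhantomSpec.clean(n_px=20, seed=1))


@pytest.fixture(scope="session")
def clean_multiset(clean_phantom):
    blocks = {k: unfold(c) for k, c in clean_phantom["cubes"].items()}
    return assemble(dict(zip(blocks, balance(list(blocks.values())))))


@pytest.fixture(scope="session")
def clean_unmix(clean_multiset):
    cs = hf.ConstraintSet(4).set_nonneg("C").set_nonneg("S")
    return hf.run_mcr_als(clean_multiset, 4, constraints=cs)


@pytest.fixture(scope="session")
def misaligned_phantom():
    """Noiseless phantom with pixel-size mismatch and rigid misalignment."""
    spec = PhantomSpec(
        n_components=5,
        transforms={
            (s, "fluorescence"): hf.RigidTransform(dx=12.0, dy=-9.0, theta=3.0)
            for s in range(3)
        }
        | {
            (s, "raman"): hf.RigidTransform(dx=2.0, dy=1.5, theta=-3.0)
            for s in range(3)
        },
        seed=1,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def e2e_run(misaligned_phantom, tmp_path_factory):
    """Full pipeline run on the noiseless misaligned phantom."""
    out = tmp_path_factory.mktemp("e2e")
    cfg = RunConfig(
        output_dir=str(out),
        reference="ftir",
        plans={
            "fluorescence": PreprocessPlan(bin_factor=12),
            "raman": PreprocessPlan(),
            "ftir": PreprocessPlan(),
        },
        n_components=5,
        constraints=hf.ConstraintSet(5).set_nonneg("C").set_nonneg("S"),
    )
    result = run_pipeline(cfg, cubes=misaligned_phantom["cubes"])
    return {"config": cfg, "result": result, "out": out}
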