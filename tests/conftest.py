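import numpy as np
import pytest

from iterlie import (
    AssayContext,
    CompoundRecord,
    EnergyDataset,
    FreeStateAverage,
    GeneratorConfig,
    SimulationAverage,
    ThermodynamicContext,
    generate,
)


@pytest.fixture
def thermo():
    return ThermodynamicContext()


@pytest.fixture
def assay():
    return AssayContext()


@pytest.fixture
def noiseless_dataset():
    """Synthetic dataset that satisfies the LIE model exactly."""
    config = GeneratorConfig(
        n_compounds=10,
        replicate_noise_sigma=0.0,
        experimental_noise_sigma=0.0,
        seed=7,
        n_train=6,
    )
    dataset, truth = generate(config)
    return dataset, truth, config


@pytest.fixture
def small_dataset():
    """Hand-sized dataset: 1 compound, 2 templates x 3 poses x 2 replicates."""
    rng = np.random.default_rng(11)
    sims = []
    for t in ("CHZ170", "PPD70"):
        for p in ("I", "II", "III"):
            for r in ("r1", "r2"):
                sims.append(
                    SimulationAverage(
                        compound_id="c1",
                        template_id=t,
                        pose_id=p,
                        replicate_id=r,
                        v_vdw_bound=float(rng.normal(-130, 10)),
                        v_el_bound=float(rng.normal(-230, 10)),
                    )
                )
    return EnergyDataset(
        simulations=sims,
        free_states=[FreeStateAverage("c1", -40.0, -200.0)],
        compounds=[CompoundRecord("c1", dg_exp=-35.0, role="train")],
    )
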