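"""Synthetic energy datasets with known ground truth.

Real inputs to the method are ensemble-average interaction energies from
MD simulations that this package deliberately does not run. The generator
emulates their statistical structure instead: per compound, a handful of
bound-state simulations (templates × poses) whose single-simulation LIE
estimates at the true (α*, β*) spread by a few k_B·T — so Boltzmann
weighting is non-trivial — plus replicate noise on the simulation averages
and Gaussian noise on the experimental free energies. Because the data are
constructed to satisfy the model exactly at zero noise, calibration must
recover (α*, β*) and every ΔG exactly in that limit, which is the
generator's main diagnostic role.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    CompoundRecord,
    EnergyDataset,
    FreeStateAverage,
    SimulationAverage,
    ThermodynamicContext,
)
from .engine import DeltaEnergies, dg_combined
from .errors import ValidationError
from .poses import PoseSet


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped defaults: 17 compounds, 2 templates × 3 poses × 2 replicates.

    ``pose_dg_spread`` (kJ mol⁻¹) is the standard deviation of the
    per-simulation LIE estimates around each compound's mean; the default
    7.5 kJ mol⁻¹ is about 3 k_B·T at 300 K, enough that weights differ
    markedly between poses. Noise sigmas are standard deviations of
    Gaussian perturbations on replicate energy averages and on ΔG_exp.
    """

    n_compounds: int = 17
    n_templates: int = 2
    n_poses_per_template: int = 3
    n_replicates: int = 2
    true_alpha: float = 0.22
    true_beta: float = 0.10
    pose_dg_spread: float = 7.5
    replicate_noise_sigma: float = 1.0
    experimental_noise_sigma: float = 2.0
    seed: int = 0
    n_train: int | None = 9  # first n_train compounds get role "train"

    def __post_init__(self) -> None:
        counts = (
            self.n_compounds,
            self.n_templates,
            self.n_poses_per_template,
            self.n_replicates,
        )
        if any(c < 1 for c in counts):
            raise ValidationError("all counts must be >= 1")
        if (
            self.pose_dg_spread < 0
            or self.replicate_noise_sigma < 0
            or self.experimental_noise_sigma < 0
        ):
            raise ValidationError("spread and noise sigmas must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset."""

    config: GeneratorConfig
    true_dg: dict[str, float] = field(default_factory=dict)
    true_weights: dict[str, list[float]] = field(default_factory=dict)


# generator anchors: energy-difference scales typical of drug-sized ligands
# binding a CYP active site, chosen so that at (0.22, 0.10) the true dG lands
# in the high-micromolar-to-low-nanomolar window (about -48 to -27 kJ/mol)
_D_VDW_MEAN, _D_VDW_SD = -100.0, 20.0
_D_EL_MEAN, _D_EL_SD = -30.0, 15.0
_V_VDW_FREE_MEAN, _V_VDW_FREE_SD = -40.0, 5.0
_V_EL_FREE_MEAN, _V_EL_FREE_SD = -200.0, 30.0


def _per_channel_sigmas(config: GeneratorConfig) -> tuple[float, float]:
    """Split pose_dg_spread between the vdW and electrostatic channels.

    Chosen so that sd(α*·d_vdw + β*·d_el) = pose_dg_spread with equal
    contributions from both channels; a zero coefficient routes the whole
    spread through the other channel (falling back to raw-energy spread
    when both vanish).
    """
    a, b = abs(config.true_alpha), abs(config.true_beta)
    s = config.pose_dg_spread
    if a == 0 and b == 0:
        return s, s
    if a == 0:
        return 0.0, s / b
    if b == 0:
        return s / a, 0.0
    return s / (np.sqrt(2) * a), s / (np.sqrt(2) * b)


def generate(
    config: GeneratorConfig,
    thermo: ThermodynamicContext | None = None,
) -> tuple[EnergyDataset, SyntheticTruth]:
    """Generate an energy dataset plus its ground truth, reproducibly.

    Per compound: draw a free state and a base (ΔV_vdw, ΔV_el); per
    simulation, perturb both channels so single-simulation LIE estimates
    spread by ``pose_dg_spread``; per replicate, add Gaussian noise to the
    bound averages. The true ΔG is the Boltzmann-weighted combination at
    (α*, β*) of the noiseless simulation values, and ΔG_exp adds
    experimental noise on top.
    """
    thermo = thermo or ThermodynamicContext()
    rng = np.random.default_rng(config.seed)
    s_vdw, s_el = _per_channel_sigmas(config)
    n_sims = config.n_templates * config.n_poses_per_template

    sims: list[SimulationAverage] = []
    free_states: list[FreeStateAverage] = []
    compounds: list[CompoundRecord] = []
    truth = SyntheticTruth(config=config)
    n_train = config.n_train if config.n_train is not None else config.n_compounds

    for c in range(config.n_compounds):
        cid = f"c{c + 1:02d}"
        v_vdw_free = rng.normal(_V_VDW_FREE_MEAN, _V_VDW_FREE_SD)
        v_el_free = rng.normal(_V_EL_FREE_MEAN, _V_EL_FREE_SD)
        base_d_vdw = rng.normal(_D_VDW_MEAN, _D_VDW_SD)
        base_d_el = rng.normal(_D_EL_MEAN, _D_EL_SD)
        d_vdw = base_d_vdw + rng.normal(0.0, s_vdw, size=n_sims)
        d_el = base_d_el + rng.normal(0.0, s_el, size=n_sims)

        deltas = []
        i = 0
        for t in range(config.n_templates):
            for p in range(config.n_poses_per_template):
                template_id = f"T{t + 1}"
                pose_id = ("I", "II", "III", "IV", "V")[p] if p < 5 else f"P{p + 1}"
                deltas.append(
                    DeltaEnergies(
                        compound_id=cid,
                        simulation_key=(template_id, pose_id),
                        d_vdw=float(d_vdw[i]),
                        d_el=float(d_el[i]),
                    )
                )
                for r in range(config.n_replicates):
                    sims.append(
                        SimulationAverage(
                            compound_id=cid,
                            template_id=template_id,
                            pose_id=pose_id,
                            replicate_id=f"r{r + 1}",
                            v_vdw_bound=float(
                                v_vdw_free
                                + d_vdw[i]
                                + rng.normal(0.0, config.replicate_noise_sigma)
                            ),
                            v_el_bound=float(
                                v_el_free
                                + d_el[i]
                                + rng.normal(0.0, config.replicate_noise_sigma)
                            ),
                        )
                    )
                i += 1
        free_states.append(
            FreeStateAverage(
                compound_id=cid,
                v_vdw_free=float(v_vdw_free),
                v_el_free=float(v_el_free),
            )
        )
        pred = dg_combined(config.true_alpha, config.true_beta, deltas, thermo)
        truth.true_dg[cid] = pred.dg_calc
        truth.true_weights[cid] = list(pred.weights.weights)
        dg_exp = pred.dg_calc + rng.normal(0.0, config.experimental_noise_sigma)
        compounds.append(
            CompoundRecord(
                compound_id=cid,
                dg_exp=float(dg_exp),
                role="train" if c < n_train else "test",
            )
        )

    dataset = EnergyDataset(
        simulations=sims, free_states=free_states, compounds=compounds
    )
    dataset.validate()
    return dataset, truth


def generate_pose_cloud(
    n_blobs: int,
    poses_per_blob: int,
    blob_sigma: float,
    separation: float,
    seed: int,
    n_atoms: int = 10,
    ligand_id: str = "synthetic",
    template_id: str = "T1",
) -> tuple[PoseSet, np.ndarray]:
    """Synthetic docked-pose cloud: k Gaussian blobs of rigid poses, in nm.

    Blob centers sit ``separation`` apart along the x axis; each pose is a
    common random atom skeleton translated to its blob center with per-atom
    Gaussian jitter of ``blob_sigma``. Returns the pose set and the true
    blob label of every pose (poses are emitted blob by blob).
    """
    if n_blobs < 1 or poses_per_blob < 1:
        raise ValidationError("n_blobs and poses_per_blob must be >= 1")
    if blob_sigma < 0 or separation < 0:
        raise ValidationError("blob_sigma and separation must be >= 0")
    rng = np.random.default_rng(seed)
    skeleton = rng.normal(0.0, 0.15, size=(n_atoms, 3))  # ~ligand-sized, nm
    coords = []
    labels = []
    for b in range(n_blobs):
        center = np.array([b * separation, 0.0, 0.0])
        for _ in range(poses_per_blob):
            jitter = rng.normal(0.0, blob_sigma, size=(n_atoms, 3))
            coords.append(skeleton + center + jitter)
            labels.append(b)
    return (
        PoseSet(
            ligand_id=ligand_id,
            template_id=template_id,
            coords=np.stack(coords),
        ),
        np.array(labels),
    )
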