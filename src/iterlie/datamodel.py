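"""Domain types shared across the package.

Units are fixed throughout: energies in kJ mol⁻¹, concentrations in molar
(M), temperatures in kelvin, lengths in nm. IC50 values given in μM by data
files are converted to molar at load time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError

#: Boltzmann constant times Avogadro's number, kJ mol⁻¹ K⁻¹. Shared by the
#: Boltzmann weighting and the gas constant R of the affinity conversion.
K_B = 0.0083145


@dataclass(frozen=True)
class ThermodynamicContext:
    """Temperatures entering the method.

    ``temperature_weighting`` is the simulation temperature T used in the
    Boltzmann weights (production MD at 300 K); ``temperature_assay`` is the
    temperature of the inhibition assay used when converting IC50 values to
    free energies (310 K, physiological).
    """

    temperature_weighting: float = 300.0
    temperature_assay: float = 310.0

    def __post_init__(self) -> None:
        if self.temperature_weighting <= 0 or self.temperature_assay <= 0:
            raise ValidationError("temperatures must be positive (kelvin)")

    @property
    def kt_weighting(self) -> float:
        """k_B·T for the weighting temperature, kJ mol⁻¹."""
        return K_B * self.temperature_weighting

    @property
    def rt_assay(self) -> float:
        """R·T for the assay temperature, kJ mol⁻¹ (R = k_B·N_A numerically)."""
        return K_B * self.temperature_assay


@dataclass(frozen=True)
class AssayContext:
    """Competitive-inhibition assay constants for the Cheng–Prusoff relation.

    ``substrate_conc`` ([S]) and ``km`` (K_m) in molar. [S] = 0 is allowed and
    gives the no-substrate limit Ki = IC50.
    """

    substrate_conc: float = 1.5e-6
    km: float = 0.5e-6

    def __post_init__(self) -> None:
        if self.substrate_conc < 0:
            raise ValidationError("substrate concentration must be >= 0")
        if self.km <= 0:
            raise ValidationError("Km must be positive")


@dataclass
class CompoundRecord:
    """One ligand: identity, experimental affinity and assay context.

    ``ic50`` is in molar, ``dg_exp`` in kJ mol⁻¹; at least one must be present
    for train/test compounds. ``role`` is ``"train"``, ``"test"`` or
    ``"query"`` (no experimental data required).
    """

    compound_id: str
    ic50: float | None = None
    dg_exp: float | None = None
    molar_mass: float | None = None
    net_charge: int | None = None
    role: str = "train"

    def __post_init__(self) -> None:
        if self.role not in ("train", "test", "query"):
            raise ValidationError(
                f"compound {self.compound_id}: role must be train/test/query, "
                f"got {self.role!r}"
            )
        if self.role in ("train", "test") and self.ic50 is None and self.dg_exp is None:
            raise ValidationError(
                f"compound {self.compound_id}: {self.role} compounds need "
                "ic50 or dg_exp"
            )
        if self.ic50 is not None and not self.ic50 > 0:
            raise ValidationError(
                f"compound {self.compound_id}: ic50 must be positive"
            )
        if self.dg_exp is not None and not math.isfinite(self.dg_exp):
            raise ValidationError(
                f"compound {self.compound_id}: dg_exp must be finite"
            )


@dataclass(frozen=True)
class SimulationAverage:
    """Ensemble-average bound-state interaction energies of one MD run.

    Keyed by (compound, template, pose, replicate); energies in kJ mol⁻¹.
    ``pose_id`` is the cluster rank (I/II/III) of the starting orientation and
    ``template_id`` names the protein conformation the run started from.
    """

    compound_id: str
    template_id: str
    pose_id: str
    replicate_id: str
    v_vdw_bound: float
    v_el_bound: float
    n_frames: int | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.v_vdw_bound) and math.isfinite(self.v_el_bound)):
            raise ValidationError(
                f"simulation {self.key}: bound-state energies must be finite"
            )
        if self.n_frames is not None and self.n_frames <= 0:
            raise ValidationError(f"simulation {self.key}: n_frames must be positive")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.compound_id, self.template_id, self.pose_id, self.replicate_id)


@dataclass(frozen=True)
class FreeStateAverage:
    """Ensemble-average ligand–water interaction energies of the unbound ligand."""

    compound_id: str
    v_vdw_free: float
    v_el_free: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.v_vdw_free) and math.isfinite(self.v_el_free)):
            raise ValidationError(
                f"free state {self.compound_id}: energies must be finite"
            )


@dataclass
class EnergyDataset:
    """Bound-state simulations, free-state averages and compound records.

    Construction enforces key uniqueness; :meth:`validate` additionally checks
    cross-table coverage over whichever tables are populated (a bound-only
    dataset is legal while assembling inputs).
    """

    simulations: list[SimulationAverage] = field(default_factory=list)
    free_states: list[FreeStateAverage] = field(default_factory=list)
    compounds: list[CompoundRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._check_unique_keys()

    def _check_unique_keys(self) -> None:
        seen: dict[tuple, int] = {}
        dups = []
        for i, sim in enumerate(self.simulations):
            if sim.key in seen:
                dups.append((sim.key, seen[sim.key], i))
            seen[sim.key] = i
        if dups:
            lines = ", ".join(
                f"{key} at rows {a} and {b}" for key, a, b in dups
            )
            raise ValidationError(f"duplicate simulation keys: {lines}")
        free_seen = set()
        for fs in self.free_states:
            if fs.compound_id in free_seen:
                raise ValidationError(
                    f"duplicate free-state entry for compound {fs.compound_id}"
                )
            free_seen.add(fs.compound_id)
        comp_seen = set()
        for c in self.compounds:
            if c.compound_id in comp_seen:
                raise ValidationError(
                    f"duplicate compound record {c.compound_id}"
                )
            comp_seen.add(c.compound_id)

    def validate(self) -> None:
        """Check cross-table coverage invariants.

        Raises :class:`ValidationError` if a simulated compound lacks a
        free-state entry (when free states are present) or a train/test
        compound lacks simulations (when simulations are present).
        """
        self._check_unique_keys()
        if self.free_states:
            have_free = {fs.compound_id for fs in self.free_states}
            missing = sorted(
                {s.compound_id for s in self.simulations} - have_free
            )
            if missing:
                raise ValidationError(
                    f"no free-state entry for simulated compounds: {missing}"
                )
        if self.simulations and self.compounds:
            have_sims = {s.compound_id for s in self.simulations}
            missing = sorted(
                c.compound_id
                for c in self.compounds
                if c.role in ("train", "test") and c.compound_id not in have_sims
            )
            if missing:
                raise ValidationError(
                    f"no simulations for train/test compounds: {missing}"
                )

    # -- convenience lookups -------------------------------------------------

    def compound(self, compound_id: str) -> CompoundRecord:
        for c in self.compounds:
            if c.compound_id == compound_id:
                return c
        from .errors import DataLookupError

        raise DataLookupError(f"unknown compound {compound_id!r}")

    def free_state(self, compound_id: str) -> FreeStateAverage:
        for fs in self.free_states:
            if fs.compound_id == compound_id:
                return fs
        from .errors import DataLookupError

        raise DataLookupError(f"no free-state entry for compound {compound_id!r}")

    def simulations_for(self, compound_id: str) -> list[SimulationAverage]:
        return [s for s in self.simulations if s.compound_id == compound_id]

    def compound_ids(self) -> list[str]:
        if self.compounds:
            return [c.compound_id for c in self.compounds]
        return sorted({s.compound_id for s in self.simulations})
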