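"""Readers and writers for the tabular energy format, compounds and models.

Three flat CSV tables mirror the (compound × template × pose × replicate)
structure of the data:

bound-state simulations
    ``compound_id,template_id,pose_id,replicate_id,v_vdw_bound,v_el_bound[,n_frames]``
free states
    ``compound_id,v_vdw_free,v_el_free``
compounds
    ``compound_id,role[,ic50_um][,dg_exp_kj_per_mol][,molar_mass_g_per_mol][,net_charge_e]``

All files are UTF-8 CSV with a decimal point and no thousands separators.
IC50 columns are stored in μM and converted to molar at load. Calibrated
models round-trip through a documented JSON layout.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from pathlib import Path
from typing import Any

import pandas as pd

from .datamodel import (
    CompoundRecord,
    EnergyDataset,
    FreeStateAverage,
    SimulationAverage,
    ThermodynamicContext,
)
from .errors import SchemaError, ValidationError

BOUND_COLUMNS = [
    "compound_id",
    "template_id",
    "pose_id",
    "replicate_id",
    "v_vdw_bound",
    "v_el_bound",
]
FREE_COLUMNS = ["compound_id", "v_vdw_free", "v_el_free"]


def _require_columns(df: pd.DataFrame, required: list[str], path: Any) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _opt_float(value: Any) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_bound_table(path: str | Path) -> list[SimulationAverage]:
    """Read the bound-state simulation table."""
    df = pd.read_csv(path, dtype={c: str for c in BOUND_COLUMNS[:4]},
                     float_precision="round_trip")
    _require_columns(df, BOUND_COLUMNS, path)
    sims = []
    for row in df.itertuples(index=False):
        n_frames = getattr(row, "n_frames", None)
        n_frames = _opt_float(n_frames)
        sims.append(
            SimulationAverage(
                compound_id=row.compound_id,
                template_id=row.template_id,
                pose_id=row.pose_id,
                replicate_id=row.replicate_id,
                v_vdw_bound=float(row.v_vdw_bound),
                v_el_bound=float(row.v_el_bound),
                n_frames=int(n_frames) if n_frames is not None else None,
            )
        )
    return sims


def read_free_table(path: str | Path) -> list[FreeStateAverage]:
    """Read the free-state (ligand in water) table."""
    df = pd.read_csv(path, dtype={"compound_id": str}, float_precision="round_trip")
    _require_columns(df, FREE_COLUMNS, path)
    return [
        FreeStateAverage(
            compound_id=row.compound_id,
            v_vdw_free=float(row.v_vdw_free),
            v_el_free=float(row.v_el_free),
        )
        for row in df.itertuples(index=False)
    ]


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compounds table; ``ic50_um`` is converted from μM to molar."""
    df = pd.read_csv(path, dtype={"compound_id": str, "role": str},
                     float_precision="round_trip")
    _require_columns(df, ["compound_id"], path)
    records = []
    for row in df.itertuples(index=False):
        ic50_um = _opt_float(getattr(row, "ic50_um", None))
        charge = _opt_float(getattr(row, "net_charge_e", None))
        records.append(
            CompoundRecord(
                compound_id=row.compound_id,
                ic50=ic50_um * 1e-6 if ic50_um is not None else None,
                dg_exp=_opt_float(getattr(row, "dg_exp_kj_per_mol", None)),
                molar_mass=_opt_float(getattr(row, "molar_mass_g_per_mol", None)),
                net_charge=int(charge) if charge is not None else None,
                role=getattr(row, "role", "train") or "train",
            )
        )
    return records


def read_energy_table(
    bound_path: str | Path,
    free_path: str | Path | None = None,
    compounds_path: str | Path | None = None,
) -> EnergyDataset:
    """Assemble an :class:`EnergyDataset` from up to three CSV tables.

    Replicate rows are preserved un-merged. Coverage invariants are checked
    over whichever tables were supplied; duplicate keys and non-finite
    energies always raise :class:`ValidationError`.
    """
    dataset = EnergyDataset(
        simulations=read_bound_table(bound_path),
        free_states=read_free_table(free_path) if free_path else [],
        compounds=read_compound_table(compounds_path) if compounds_path else [],
    )
    dataset.validate()
    return dataset


def write_energy_table(
    dataset: EnergyDataset,
    bound_path: str | Path,
    free_path: str | Path | None = None,
    compounds_path: str | Path | None = None,
) -> None:
    """Write a dataset back to CSV; inverse of :func:`read_energy_table`."""
    rows = [
        {
            "compound_id": s.compound_id,
            "template_id": s.template_id,
            "pose_id": s.pose_id,
            "replicate_id": s.replicate_id,
            "v_vdw_bound": s.v_vdw_bound,
            "v_el_bound": s.v_el_bound,
            "n_frames": s.n_frames,
        }
        for s in dataset.simulations
    ]
    df = pd.DataFrame(rows, columns=BOUND_COLUMNS + ["n_frames"])
    if df["n_frames"].isna().all():
        df = df.drop(columns=["n_frames"])
    df.to_csv(bound_path, index=False, float_format="%.17g")
    if free_path is not None:
        pd.DataFrame(
            [
                {
                    "compound_id": f.compound_id,
                    "v_vdw_free": f.v_vdw_free,
                    "v_el_free": f.v_el_free,
                }
                for f in dataset.free_states
            ],
            columns=FREE_COLUMNS,
        ).to_csv(free_path, index=False, float_format="%.17g")
    if compounds_path is not None:
        write_compound_table(dataset.compounds, compounds_path)


def write_compound_table(
    compounds: list[CompoundRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "compound_id": c.compound_id,
                "role": c.role,
                "ic50_um": c.ic50 * 1e6 if c.ic50 is not None else None,
                "dg_exp_kj_per_mol": c.dg_exp,
                "molar_mass_g_per_mol": c.molar_mass,
                "net_charge_e": c.net_charge,
            }
            for c in compounds
        ],
        columns=[
            "compound_id",
            "role",
            "ic50_um",
            "dg_exp_kj_per_mol",
            "molar_mass_g_per_mol",
            "net_charge_e",
        ],
    ).to_csv(path, index=False, float_format="%.17g")


def load_aryloxypropanolamines(with_printed_dg: bool = False) -> list[CompoundRecord]:
    """Load the packaged fixture of 17 CYP 2D6 aryloxypropanolamine ligands.

    Nine training and eight test compounds with IC50 values (0.03–100 μM)
    from a single AMMC-inhibition study, plus molar masses and net charges.
    By default ``dg_exp`` is left unset so that free energies are derived
    from IC50 through the Cheng–Prusoff conversion; pass
    ``with_printed_dg=True`` to carry the tabulated ΔG_exp values instead.
    """
    resource = importlib.resources.files("iterlie.data").joinpath(
        "aryloxypropanolamines.csv"
    )
    with importlib.resources.as_file(resource) as path:
        records = read_compound_table(path)
    if not with_printed_dg:
        for rec in records:
            rec.dg_exp = None
    return records


# -- model JSON serialization ------------------------------------------------


def model_to_dict(model: "LIEModel") -> dict:  # noqa: F821
    from .engine import LIEModel  # local import avoids a cycle

    assert isinstance(model, LIEModel)
    return {
        "alpha": model.alpha,
        "beta": model.beta,
        "temperature_weighting": model.thermo.temperature_weighting,
        "temperature_assay": model.thermo.temperature_assay,
        "training_compound_ids": list(model.training_compound_ids),
        "converged": model.converged,
        "n_iterations": model.n_iterations,
        "final_weights": {
            cid: {
                "simulation_keys": [list(k) for k in wv.simulation_keys],
                "weights": list(wv.weights),
                "dg_per_sim": list(wv.dg_per_sim),
            }
            for cid, wv in model.final_weights.items()
        },
    }


def write_model(model: "LIEModel", path: str | Path) -> None:  # noqa: F821
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2))


def read_model(path: str | Path) -> "LIEModel":  # noqa: F821
    from .engine import LIEModel, WeightVector

    raw = json.loads(Path(path).read_text())
    try:
        return LIEModel(
            alpha=float(raw["alpha"]),
            beta=float(raw["beta"]),
            thermo=ThermodynamicContext(
                temperature_weighting=raw["temperature_weighting"],
                temperature_assay=raw["temperature_assay"],
            ),
            training_compound_ids=list(raw["training_compound_ids"]),
            converged=bool(raw["converged"]),
            n_iterations=int(raw["n_iterations"]),
            final_weights={
                cid: WeightVector(
                    simulation_keys=[tuple(k) for k in wv["simulation_keys"]],
                    weights=list(wv["weights"]),
                    dg_per_sim=list(wv["dg_per_sim"]),
                )
                for cid, wv in raw.get("final_weights", {}).items()
            },
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: model JSON missing field {exc}") from exc
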