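"""Cheng–Prusoff conversion of inhibition data to binding free energies.

For a competitive inhibitor, the measured IC50 relates to the inhibition
constant through Ki = IC50 / (1 + [S]/Km); the experimental binding free
energy follows as ΔG_exp = R·T·ln(Ki / 1 M), i.e. the standard state is 1 M
and Ki enters dimensionless. With the assay used for the packaged compound
set ([S] = 1.5 μM, Km = 0.5 μM, T = 310 K) IC50 values of 0.03–100 μM map
onto ΔG_exp between −48.2 and −27.3 kJ mol⁻¹.
"""

from __future__ import annotations

import logging
import math

from .datamodel import AssayContext, CompoundRecord, ThermodynamicContext
from .errors import ValidationError

logger = logging.getLogger(__name__)


def ki_from_ic50(ic50: float, assay: AssayContext) -> float:
    """Inhibition constant Ki (molar) from an IC50 (molar).

    Ki = IC50 / (1 + [S]/Km). With [S] = 0 this reduces to Ki = IC50.
    """
    if not ic50 > 0:
        raise ValidationError(f"ic50 must be positive, got {ic50}")
    return ic50 / (1.0 + assay.substrate_conc / assay.km)


def dg_from_ic50(
    ic50: float, assay: AssayContext, thermo: ThermodynamicContext
) -> float:
    """Binding free energy ΔG_exp = R·T_assay·ln(Ki/1 M), kJ mol⁻¹.

    Strictly increasing in IC50 and log-linear: dividing the IC50 by e
    lowers ΔG_exp by exactly R·T_assay.
    """
    ki = ki_from_ic50(ic50, assay)
    return thermo.rt_assay * math.log(ki)


def convert_compound_set(
    compounds: list[CompoundRecord],
    assay: AssayContext,
    thermo: ThermodynamicContext,
) -> list[CompoundRecord]:
    """Fill ``dg_exp`` for every compound from its IC50.

    Compounds that already carry ``dg_exp`` pass through unchanged. Returns
    new records (inputs are not mutated) and logs the min/max of the
    converted values.
    """
    out: list[CompoundRecord] = []
    converted: list[float] = []
    for c in compounds:
        if c.dg_exp is not None:
            out.append(c)
            continue
        if c.ic50 is None:
            raise ValidationError(
                f"compound {c.compound_id}: neither ic50 nor dg_exp present"
            )
        dg = dg_from_ic50(c.ic50, assay, thermo)
        converted.append(dg)
        out.append(
            CompoundRecord(
                compound_id=c.compound_id,
                ic50=c.ic50,
                dg_exp=dg,
                molar_mass=c.molar_mass,
                net_charge=c.net_charge,
                role=c.role,
            )
        )
    if converted:
        logger.info(
            "converted %d IC50 values; dG_exp range %.2f to %.2f kJ/mol",
            len(converted),
            min(converted),
            max(converted),
        )
    return out
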