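"""Model-quality assessment: exhaustive train/test permutation scanning,
per-template weight decomposition, and a principal-axes applicability check.

The permutation scan recalibrates the LIE model for every way of splitting
the compound set into a fixed-size training set and its complement, and
scores each split by the total root-mean-square error over all compounds —
the exhaustive analogue of cross-validation for small compound series.

The applicability check asks whether a query compound's weighted energy
differences, scaled by the model coefficients into the (α·ΔV_vdw, β·ΔV_el)
plane, lie within the training cloud: displacement from the training
centroid is measured along each principal axis of the training covariance
in units of that axis's spread, and a compound farther than a multiplier
(default 2) along any axis is flagged as outside the model's domain.
"""

from __future__ import annotations

import csv
import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datamodel import EnergyDataset, ThermodynamicContext
from .engine import (
    CalibrationOptions,
    LIEModel,
    calibrate,
    predict,
    rmse,
)
from .errors import DegenerateDesignError, InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SplitResult:
    """One train/test partition with its refit model and error summary."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    alpha: float
    beta: float
    rmse_train: float
    sdep_test: float
    rmse_tot: float
    converged: bool


@dataclass
class ApplicabilityReport:
    """Principal-axes domain scores of one compound against a trained model."""

    compound_id: str
    coordinates: tuple[float, float]  # (alpha * dVvdw, beta * dVel), weighted
    pa_scores: tuple[float, float]  # standardized displacement per axis
    flagged: bool
    threshold_multiplier: float


def enumerate_splits(
    compound_ids, train_size: int
):
    """Yield every (train, test) partition of the given size exactly once.

    Deterministic lexicographic order over the sorted compound ids; the
    number of partitions is C(n, train_size).
    """
    ids = sorted(compound_ids)
    n = len(ids)
    if not 0 < train_size < n:
        raise ValidationError(
            f"train_size must be in (0, {n}), got {train_size}"
        )
    for train in itertools.combinations(ids, train_size):
        train_set = set(train)
        test = tuple(i for i in ids if i not in train_set)
        yield train, test


def permutation_scan(
    dataset: EnergyDataset,
    thermo: ThermodynamicContext,
    train_size: int,
    options: CalibrationOptions | None = None,
    stream_path: str | Path | None = None,
) -> list[SplitResult]:
    """Calibrate and evaluate a LIE model for every train/test partition.

    Each split refits (α, β) on its training side only, predicts all
    compounds, and records RMSE over the training side, SDEP over the test
    side and RMSE_tot over everything. Non-converged calibrations are
    recorded with ``converged=False``, never dropped. When ``stream_path``
    is given, rows are appended to a CSV as they are produced so arbitrarily
    large scans run in bounded memory; ordering is deterministic, so results
    reproduce without a seed.
    """
    compounds = {c.compound_id: c for c in dataset.compounds}
    missing = [cid for cid, c in compounds.items() if c.dg_exp is None]
    if missing:
        raise ValidationError(f"compounds without dg_exp: {sorted(missing)}")
    base = options or CalibrationOptions()
    results: list[SplitResult] = []
    writer = None
    handle = None
    if stream_path is not None:
        handle = open(stream_path, "w", newline="")
        writer = csv.writer(handle)
        writer.writerow(
            ["train_ids", "alpha", "beta", "rmse_train", "sdep_test",
             "rmse_tot", "converged"]
        )
    try:
        for train, test in enumerate_splits(compounds, train_size):
            opts = CalibrationOptions(
                tol=base.tol,
                max_iterations=base.max_iterations,
                damping=base.damping,
                training_ids=train,
            )
            model = calibrate(dataset, thermo, opts)
            preds = {
                cid: predict(model, dataset, cid) for cid in compounds
            }
            res = SplitResult(
                train_ids=train,
                test_ids=test,
                alpha=model.alpha,
                beta=model.beta,
                rmse_train=rmse(preds, [compounds[i] for i in train]),
                sdep_test=rmse(preds, [compounds[i] for i in test]),
                rmse_tot=rmse(preds, list(compounds.values())),
                converged=model.converged,
            )
            results.append(res)
            if writer is not None:
                writer.writerow(
                    ["|".join(train), res.alpha, res.beta, res.rmse_train,
                     res.sdep_test, res.rmse_tot, res.converged]
                )
    finally:
        if handle is not None:
            handle.close()
    best = best_split(results)
    logger.info(
        "scanned %d splits; best rmse_tot=%.3f kJ/mol (train=%s)",
        len(results), best.rmse_tot, ",".join(best.train_ids),
    )
    return results


def best_split(results: list[SplitResult]) -> SplitResult:
    """The partition with minimal RMSE_tot (first one on ties)."""
    if not results:
        raise ValidationError("no split results")
    return min(results, key=lambda r: r.rmse_tot)


def weight_decomposition(
    model: LIEModel, dataset: EnergyDataset
) -> dict[str, dict[str, float]]:
    """Per-compound Boltzmann weight summed over each protein template.

    Shows which template's simulations dominate each compound's combined
    free energy; the sums over templates equal 1 per compound.
    """
    out: dict[str, dict[str, float]] = {}
    for cid in dataset.compound_ids():
        pred = predict(model, dataset, cid)
        by_template: dict[str, float] = {}
        for (template, _pose), w in zip(
            pred.weights.simulation_keys, pred.weights.weights
        ):
            by_template[template] = by_template.get(template, 0.0) + w
        out[cid] = by_template
    return out


def _weighted_coordinates(
    model: LIEModel, dataset: EnergyDataset, compound_id: str
) -> tuple[float, float]:
    from .engine import delta_energies

    deltas = delta_energies(dataset, compound_id)
    pred = predict(model, dataset, compound_id)
    w = np.asarray(pred.weights.weights)
    x = model.alpha * float(np.dot(w, [d.d_vdw for d in deltas]))
    y = model.beta * float(np.dot(w, [d.d_el for d in deltas]))
    return x, y


def applicability_check(
    model: LIEModel,
    dataset: EnergyDataset,
    query_ids,
    multiplier: float = 2.0,
    spread: str = "std",
) -> list[ApplicabilityReport]:
    """Flag compounds outside the training cloud's principal-axes envelope.

    The training compounds' weighted coordinates (α·ΣW·ΔV_vdw, β·ΣW·ΔV_el)
    define a centroid and 2×2 covariance; its eigenvectors are the principal
    axes. Each query's score along axis k is its absolute centered
    projection divided by that axis's spread — the standard deviation
    sqrt(λ_k) by default (``spread="std"``), or the variance λ_k itself
    (``spread="variance"``) for the literal reading of a
    "two-times-the-variance" envelope. A compound is flagged when any score
    exceeds ``multiplier``.
    """
    if spread not in ("std", "variance"):
        raise ValidationError(f"spread must be 'std' or 'variance', got {spread!r}")
    train_ids = model.training_compound_ids
    if len(train_ids) < 3:
        raise InsufficientDataError(
            "applicability check needs >= 3 training compounds for a "
            "non-degenerate covariance"
        )
    coords = np.array(
        [_weighted_coordinates(model, dataset, cid) for cid in train_ids]
    )
    centroid = coords.mean(axis=0)
    cov = np.cov(coords.T, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] <= 1e-12 * max(eigvals[-1], 1.0):
        raise DegenerateDesignError(
            "training covariance is singular along a principal axis; "
            "add training compounds with more spread"
        )
    scale = np.sqrt(eigvals) if spread == "std" else eigvals
    reports = []
    for cid in query_ids:
        xy = np.array(_weighted_coordinates(model, dataset, cid))
        proj = (xy - centroid) @ eigvecs  # projections onto the two axes
        scores = np.abs(proj) / scale
        reports.append(
            ApplicabilityReport(
                compound_id=cid,
                coordinates=(float(xy[0]), float(xy[1])),
                pa_scores=(float(scores[0]), float(scores[1])),
                flagged=bool(np.any(scores > multiplier)),
                threshold_multiplier=multiplier,
            )
        )
    return reports
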