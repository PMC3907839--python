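"""Core LIE engine: replicate merging, Boltzmann weighting, combination,
self-consistent calibration and prediction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iterlie import (
    CalibrationOptions,
    CompoundRecord,
    DeltaEnergies,
    EnergyDataset,
    FreeStateAverage,
    GeneratorConfig,
    K_B,
    SimulationAverage,
    ThermodynamicContext,
    boltzmann_weights,
    calibrate,
    combine_replicates,
    delta_energies,
    dg_combined,
    dg_single,
    generate,
    predict,
    rmse,
    sdep,
)
from iterlie.errors import (
    DataLookupError,
    DegenerateDesignError,
    InsufficientDataError,
    ValidationError,
)


def brute_force_combined(alpha, beta, d_vdw, d_el, kt):
    """Independent slow-path evaluation of the weighted LIE combination."""
    dg_i = [alpha * v + beta * e for v, e in zip(d_vdw, d_el)]
    raw = [math.exp(-g / kt) for g in dg_i]
    z = sum(raw)
    w = [r / z for r in raw]
    return sum(wi * gi for wi, gi in zip(w, dg_i)), w


def _sim(cid="c1", t="T1", p="I", r="r1", vdw=-100.0, el=-50.0, n=None):
    return SimulationAverage(cid, t, p, r, vdw, el, n_frames=n)


class TestCombineReplicates:
    def test_plain_mean_of_equal_replicates(self):
        merged = combine_replicates(
            [_sim(r="r1", vdw=-100.0), _sim(r="r2", vdw=-102.0)]
        )
        assert len(merged) == 1
        assert merged[0].v_vdw_bound == pytest.approx(-101.0)
        assert merged[0].replicate_id == "combined"

    def test_singleton_passes_through(self):
        merged = combine_replicates([_sim(vdw=-97.5)])
        assert len(merged) == 1
        assert merged[0].v_vdw_bound == -97.5

    def test_frame_weighted_mean(self):
        # oracle: (1000*(-100) + 3000*(-102)) / 4000 = -101.5
        merged = combine_replicates(
            [_sim(r="r1", vdw=-100.0, n=1000), _sim(r="r2", vdw=-102.0, n=3000)]
        )
        assert merged[0].v_vdw_bound == pytest.approx(-101.5)
        assert merged[0].n_frames == 4000

    def test_groups_kept_separate(self):
        merged = combine_replicates(
            [_sim(p="I", r="r1"), _sim(p="I", r="r2"), _sim(p="II", r="r1")]
        )
        assert {(m.template_id, m.pose_id) for m in merged} == {("T1", "I"), ("T1", "II")}


class TestDeltaEnergies:
    def _dataset(self):
        return EnergyDataset(
            simulations=[_sim(vdw=-120.0, el=-60.0)],
            free_states=[FreeStateAverage("c1", -30.0, -50.0)],
        )

    def test_subtraction(self):
        (d,) = delta_energies(self._dataset(), "c1")
        assert (d.d_vdw, d.d_el) == (-90.0, -10.0)

    def test_bound_equals_free_gives_zero(self):
        ds = EnergyDataset(
            simulations=[_sim(vdw=-30.0, el=-50.0)],
            free_states=[FreeStateAverage("c1", -30.0, -50.0)],
        )
        (d,) = delta_energies(ds, "c1")
        assert (d.d_vdw, d.d_el) == (0.0, 0.0)

    def test_cardinality_after_replicate_merge(self, small_dataset):
        deltas = delta_energies(small_dataset, "c1")
        assert len(deltas) == 6  # 2 templates x 3 poses, replicates merged
        assert [d.simulation_key for d in deltas] == sorted(
            d.simulation_key for d in deltas
        )

    def test_missing_free_state_raises(self):
        ds = EnergyDataset(simulations=[_sim()])
        with pytest.raises(DataLookupError):
            delta_energies(ds, "c1")


class TestDgSingle:
    def test_hand_arithmetic_at_published_coefficients(self):
        d = DeltaEnergies("c1", ("T1", "I"), d_vdw=-90.0, d_el=-10.0)
        assert dg_single(0.22, 0.10, d) == pytest.approx(-20.8)

    def test_zero_coefficients(self):
        d = DeltaEnergies("c1", ("T1", "I"), d_vdw=-90.0, d_el=-10.0)
        assert dg_single(0.0, 0.0, d) == 0.0

    def test_identity_on_vdw_channel(self):
        d = DeltaEnergies("c1", ("T1", "I"), d_vdw=-37.25, d_el=123.0)
        assert dg_single(1.0, 0.0, d) == -37.25


class TestBoltzmannWeights:
    def test_single_simulation_gets_unit_weight(self, thermo):
        assert boltzmann_weights([-20.0], thermo).weights == [1.0]

    def test_equal_energies_split_evenly(self, thermo):
        wv = boltzmann_weights([-20.0, -20.0], thermo)
        assert wv.weights == pytest.approx([0.5, 0.5])

    def test_analytic_ratio_ln3(self, thermo):
        gap = thermo.kt_weighting * math.log(3.0)
        wv = boltzmann_weights([0.0, gap], thermo)
        assert wv.weights == pytest.approx([0.75, 0.25], rel=1e-12)

    def test_extreme_gap_no_overflow(self, thermo):
        wv = boltzmann_weights([0.0, -5000.0], thermo)
        assert wv.weights == pytest.approx([0.0, 1.0], abs=1e-300)

    def test_empty_rejected(self, thermo):
        with pytest.raises(ValidationError):
            boltzmann_weights([], thermo)

    @settings(max_examples=100, derandomize=True)
    @given(
        dgs=st.lists(
            st.floats(min_value=-500, max_value=500), min_size=1, max_size=20
        )
    )
    def test_weights_normalize_for_any_input(self, dgs):
        wv = boltzmann_weights(dgs, ThermodynamicContext())
        assert abs(sum(wv.weights) - 1.0) <= 1e-12
        assert min(wv.weights) >= 0.0

    def test_temperature_limits(self):
        dgs = [-10.0, -12.0, -30.0]
        hot = ThermodynamicContext(temperature_weighting=1e9)
        assert boltzmann_weights(dgs, hot).weights == pytest.approx(
            [1 / 3] * 3, abs=1e-6
        )
        cold = ThermodynamicContext(temperature_weighting=1e-3)
        assert boltzmann_weights(dgs, cold).weights[2] == pytest.approx(1.0)


class TestDgCombined:
    def _deltas(self, pairs, cid="c1"):
        return [
            DeltaEnergies(cid, ("T1", f"p{i}"), v, e)
            for i, (v, e) in enumerate(pairs)
        ]

    def test_single_simulation_reduces_to_dg_single(self, thermo):
        deltas = self._deltas([(-90.0, -10.0)])
        res = dg_combined(0.22, 0.10, deltas, thermo)
        assert res.dg_calc == pytest.approx(dg_single(0.22, 0.10, deltas[0]))

    def test_identical_simulations_reduce_to_one(self, thermo):
        deltas = self._deltas([(-90.0, -10.0)] * 4)
        res = dg_combined(0.22, 0.10, deltas, thermo)
        assert res.dg_calc == pytest.approx(-20.8)
        assert res.weights.weights == pytest.approx([0.25] * 4)

    def test_matches_brute_force_oracle(self, thermo):
        pairs = [(-90.0, -10.0), (-70.0, -40.0), (-110.0, 5.0)]
        res = dg_combined(0.22, 0.10, self._deltas(pairs), thermo)
        expected, w = brute_force_combined(
            0.22, 0.10, [p[0] for p in pairs], [p[1] for p in pairs],
            thermo.kt_weighting,
        )
        assert res.dg_calc == pytest.approx(expected, rel=1e-12)
        assert res.weights.weights == pytest.approx(w, rel=1e-12)

    def test_mixed_compounds_rejected(self, thermo):
        deltas = self._deltas([(-90.0, -10.0)]) + self._deltas(
            [(-80.0, -20.0)], cid="c2"
        )
        with pytest.raises(ValidationError, match="mix"):
            dg_combined(0.22, 0.10, deltas, thermo)

    def test_bounded_by_per_simulation_estimates(self, thermo):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pairs = rng.normal([-100, -30], [20, 15], size=(5, 2))
            deltas = self._deltas([tuple(p) for p in pairs])
            res = dg_combined(0.22, 0.10, deltas, thermo)
            per_sim = [dg_single(0.22, 0.10, d) for d in deltas]
            assert min(per_sim) - 1e-9 <= res.dg_calc <= max(per_sim) + 1e-9

    def test_shift_invariance_of_weights(self, thermo):
        pairs = [(-90.0, -10.0), (-70.0, -40.0), (-110.0, 5.0)]
        base = dg_combined(0.22, 0.10, self._deltas(pairs), thermo)
        shift = 30.0  # same vdW shift on every simulation
        shifted = dg_combined(
            0.22, 0.10, self._deltas([(v + shift, e) for v, e in pairs]), thermo
        )
        assert shifted.weights.weights == pytest.approx(
            base.weights.weights, rel=1e-12
        )
        assert shifted.dg_calc == pytest.approx(
            base.dg_calc + 0.22 * shift, rel=1e-12
        )


class TestCalibrate:
    def test_noiseless_recovery_of_true_parameters(self, noiseless_dataset):
        dataset, truth, config = noiseless_dataset
        model = calibrate(dataset, ThermodynamicContext())
        assert model.converged
        assert model.alpha == pytest.approx(config.true_alpha, abs=1e-6)
        assert model.beta == pytest.approx(config.true_beta, abs=1e-6)

    def test_converged_weights_match_truth(self, noiseless_dataset):
        dataset, truth, _ = noiseless_dataset
        model = calibrate(dataset, ThermodynamicContext())
        for cid in model.training_compound_ids:
            assert model.final_weights[cid].weights == pytest.approx(
                truth.true_weights[cid], abs=1e-8
            )

    def test_single_simulation_matches_direct_least_squares(self):
        # one simulation per compound -> no weighting; closed-form lstsq oracle
        rng = np.random.default_rng(4)
        n = 8
        d_vdw = rng.normal(-100, 20, n)
        d_el = rng.normal(-30, 15, n)
        y = rng.normal(-35, 6, n)
        sims, frees, comps = [], [], []
        for i in range(n):
            cid = f"c{i}"
            sims.append(SimulationAverage(cid, "T1", "I", "r1",
                                          d_vdw[i] - 40.0, d_el[i] - 200.0))
            frees.append(FreeStateAverage(cid, -40.0, -200.0))
            comps.append(CompoundRecord(cid, dg_exp=float(y[i]), role="train"))
        ds = EnergyDataset(simulations=sims, free_states=frees, compounds=comps)
        model = calibrate(ds, ThermodynamicContext())
        coef, *_ = np.linalg.lstsq(np.column_stack([d_vdw, d_el]), y, rcond=None)
        assert model.alpha == pytest.approx(float(coef[0]), abs=1e-9)
        assert model.beta == pytest.approx(float(coef[1]), abs=1e-9)

    def test_duplicating_simulations_leaves_fit_unchanged(self, noiseless_dataset):
        dataset, _, _ = noiseless_dataset
        base = calibrate(dataset, ThermodynamicContext())
        doubled_sims = list(dataset.simulations) + [
            SimulationAverage(
                s.compound_id, s.template_id, s.pose_id, s.replicate_id + "_dup",
                s.v_vdw_bound, s.v_el_bound, s.n_frames,
            )
            for s in dataset.simulations
        ]
        doubled = EnergyDataset(
            simulations=doubled_sims,
            free_states=dataset.free_states,
            compounds=dataset.compounds,
        )
        model = calibrate(doubled, ThermodynamicContext())
        # duplicate replicates merge to the same per-state averages
        assert model.alpha == pytest.approx(base.alpha, abs=1e-9)
        assert model.beta == pytest.approx(base.beta, abs=1e-9)

    def test_too_few_compounds_rejected(self):
        ds = EnergyDataset(
            simulations=[_sim()],
            free_states=[FreeStateAverage("c1", -40.0, -200.0)],
            compounds=[CompoundRecord("c1", dg_exp=-30.0, role="train")],
        )
        with pytest.raises(InsufficientDataError):
            calibrate(ds, ThermodynamicContext())

    def test_collinear_design_rejected(self):
        sims, frees, comps = [], [], []
        for i in range(4):
            cid = f"c{i}"
            v = -80.0 - 10.0 * i
            # d_el exactly proportional to d_vdw across all compounds
            sims.append(SimulationAverage(cid, "T1", "I", "r1", v - 40.0, 0.5 * v - 200.0))
            frees.append(FreeStateAverage(cid, -40.0, -200.0))
            comps.append(CompoundRecord(cid, dg_exp=-30.0 - i, role="train"))
        ds = EnergyDataset(simulations=sims, free_states=frees, compounds=comps)
        with pytest.raises(DegenerateDesignError, match="collinear"):
            calibrate(ds, ThermodynamicContext())


class TestPredict:
    def test_training_compound_self_consistency(self, noiseless_dataset):
        dataset, _, _ = noiseless_dataset
        model = calibrate(dataset, ThermodynamicContext())
        for cid in model.training_compound_ids:
            pred = predict(model, dataset, cid)
            stored = model.final_weights[cid]
            assert pred.weights.weights == pytest.approx(stored.weights, abs=1e-7)
            combined_stored = float(
                np.dot(stored.weights, stored.dg_per_sim)
            )
            assert pred.dg_calc == pytest.approx(combined_stored, abs=1e-7)

    def test_noiseless_test_compound_recovered_exactly(self, noiseless_dataset):
        dataset, truth, _ = noiseless_dataset
        model = calibrate(dataset, ThermodynamicContext())
        for c in dataset.compounds:
            if c.role == "test":
                pred = predict(model, dataset, c.compound_id)
                assert pred.dg_calc == pytest.approx(
                    truth.true_dg[c.compound_id], abs=1e-6
                )

    def test_unknown_compound_raises(self, noiseless_dataset):
        dataset, _, _ = noiseless_dataset
        model = calibrate(dataset, ThermodynamicContext())
        with pytest.raises(DataLookupError):
            predict(model, dataset, "nope")


class TestErrorMetrics:
    def _preds(self, errors):
        from iterlie.engine import PredictionResult, WeightVector

        comps, preds = [], {}
        for i, err in enumerate(errors):
            cid = f"c{i}"
            comps.append(CompoundRecord(cid, dg_exp=-30.0, role="train"))
            preds[cid] = PredictionResult(
                cid, -30.0 + err,
                WeightVector([("T1", "I")], [1.0], [-30.0 + err]), 1,
            )
        return preds, comps

    def test_perfect_predictions_give_zero(self):
        preds, comps = self._preds([0.0, 0.0, 0.0])
        assert rmse(preds, comps) == 0.0

    def test_symmetric_errors(self):
        preds, comps = self._preds([3.0, -3.0, 3.0, -3.0])
        assert rmse(preds, comps) == pytest.approx(3.0)

    def test_matches_hand_computation(self):
        errors = [1.2, -0.7, 2.5, -3.1, 0.4]
        preds, comps = self._preds(errors)
        expected = math.sqrt(sum(e * e for e in errors) / len(errors))
        assert rmse(preds, comps) == pytest.approx(expected, rel=1e-12)

    def test_sdep_is_same_formula(self):
        preds, comps = self._preds([2.0, -2.0])
        assert sdep(preds, comps) == rmse(preds, comps)

    def test_empty_subset_rejected(self):
        preds, _ = self._preds([1.0])
        with pytest.raises(ValidationError):
            rmse(preds, [])


@settings(max_examples=100, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_combined_free_energy_matches_oracle_on_random_instances(seed):
    """Weighted combination agrees with a brute-force evaluation to 1e-10."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 8))
    d_vdw = rng.normal(-100, 25, n)
    d_el = rng.normal(-30, 15, n)
    alpha, beta = rng.normal(0.2, 0.1), rng.normal(0.1, 0.05)
    thermo = ThermodynamicContext()
    deltas = [
        DeltaEnergies("c1", ("T1", f"p{i}"), float(d_vdw[i]), float(d_el[i]))
        for i in range(n)
    ]
    res = dg_combined(alpha, beta, deltas, thermo)
    expected, _ = brute_force_combined(alpha, beta, d_vdw, d_el, thermo.kt_weighting)
    assert res.dg_calc == pytest.approx(expected, rel=1e-10, abs=1e-10)
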