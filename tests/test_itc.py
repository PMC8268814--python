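"""Enthalpogram bookkeeping, linearization and the demicellization fit."""

import numpy as np
import pytest

from bilemic import synthetic
from bilemic.exceptions import (
    InsufficientDataError,
    NoTransitionError,
    ValidationError,
)
from bilemic.itc import (
    DemicellizationEstimator,
    ITCInjectionSeries,
    aggregation_number_from_line,
    cumulative_concentrations,
    eq5_transform,
    fit_demicellization,
)
from bilemic.itc import _weighted_line
from bilemic.mass_action import monomer_concentration, monomer_derivative, params_from_cmc

TRUTH = dict(n=10.0, cmc=0.45, dH_demic=-5.0, dH_dil=-0.2)


def _series(heats, vols=None, syringe=10.0, cell=200.0):
    heats = np.asarray(heats, float)
    if vols is None:
        vols = np.full(heats.size, 2.0)
    return ITCInjectionSeries(
        syringe_conc=syringe, cell_volume=cell,
        injection_volumes=vols, heats=heats,
    )


class TestCumulativeConcentrations:
    def test_displacement_model(self):
        s = _series([0.0], vols=np.array([2.0]))
        assert cumulative_concentrations(s) == pytest.approx([0.1])
        s2 = _series([0.0, 0.0], vols=np.array([2.0, 2.0]))
        assert cumulative_concentrations(s2) == pytest.approx([0.1, 0.199])

    def test_empty_schedule(self):
        s = _series([], vols=np.array([]))
        assert cumulative_concentrations(s).size == 0

    def test_strictly_increasing(self):
        s = _series(np.zeros(30), vols=np.full(30, 2.0))
        c = cumulative_concentrations(s)
        assert np.all(np.diff(c) > 0)

    def test_injection_exceeding_cell_rejected(self):
        with pytest.raises(ValidationError):
            _series([0.0], vols=np.array([250.0]))


@pytest.fixture(scope="module")
def analytic():
    """Exact model data: heats proportional to the analytic derivative."""
    p = params_from_cmc(n=10.0, cmc=0.45)
    s_tot = np.geomspace(0.05, 5.0, 200)
    u = monomer_derivative(monomer_concentration(s_tot, p), p)
    heats = TRUTH["dH_dil"] + TRUTH["dH_demic"] * u
    return s_tot, heats


class TestEq5Transform:

    def test_exact_model_data_lie_on_theory_line(self, analytic):
        s_tot, heats = analytic
        pts = eq5_transform(heats, TRUTH["dH_demic"], TRUTH["dH_dil"], s_tot)
        intercept, slope, r2 = _weighted_line(pts.x, pts.y, pts.weights)
        assert r2 >= 0.999999
        assert intercept == pytest.approx(0.9, abs=5e-3)   # (n-1)/n
        assert slope == pytest.approx(8.1, abs=5e-2)       # (n-1)^2/n
        # line value at the transition midpoint x = 0.5
        assert intercept + 0.5 * slope == pytest.approx(4.95, abs=0.03)
        est = aggregation_number_from_line(intercept, slope)
        assert est.n == pytest.approx(10.0, rel=5e-3)

    def test_flipped_enthalpy_sign_drops_everything(self, analytic):
        s_tot, heats = analytic
        with pytest.raises(InsufficientDataError):
            eq5_transform(heats, -TRUTH["dH_demic"], TRUTH["dH_dil"], s_tot)

    def test_out_of_range_points_are_counted(self, analytic):
        s_tot, heats = analytic
        heats = heats.copy()
        heats[:3] = TRUTH["dH_dil"] + 1.5 * TRUTH["dH_demic"]  # x = 1.5
        pts = eq5_transform(heats, TRUTH["dH_demic"], TRUTH["dH_dil"], s_tot)
        assert pts.n_dropped >= 3
        assert pts.x.size + pts.n_dropped == heats.size

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            eq5_transform([1.0, 2.0], -5.0, 0.0, [1.0])


class TestAggregationNumberFromLine:
    def test_consistent_pair_is_exact(self):
        est = aggregation_number_from_line(0.9, 8.1)
        assert est.n == pytest.approx(10.0, abs=1e-6)
        assert est.consistent

    def test_slope_only_inversion(self):
        est = aggregation_number_from_line(-0.1, 8.43)  # intercept unusable
        assert est.n_from_intercept is None
        assert est.n_from_slope == pytest.approx(10.3332, abs=1e-3)
        assert est.n == pytest.approx(est.n_from_slope, abs=1e-4)

    def test_reported_pair_brackets(self):
        est = aggregation_number_from_line(0.89, 8.43)
        assert 9.1 <= est.n <= 10.5
        assert est.n_from_intercept == pytest.approx(9.0909, abs=1e-3)

    def test_inconsistent_pair_warns_not_fails(self):
        with pytest.warns(UserWarning, match="disagree"):
            est = aggregation_number_from_line(0.5, 8.1)
        assert not est.consistent

    def test_unusable_pair_rejected(self):
        with pytest.raises(ValidationError):
            aggregation_number_from_line(1.5, -2.0)


class TestFitDemicellization:
    def test_noiseless_round_trip(self, clean_fit):
        assert clean_fit.n == pytest.approx(TRUTH["n"], rel=0.02)
        assert clean_fit.dH_demic == pytest.approx(TRUTH["dH_demic"], rel=0.01)
        assert clean_fit.cmc == pytest.approx(TRUTH["cmc"], rel=0.02)
        assert clean_fit.dH_dil == pytest.approx(TRUTH["dH_dil"], rel=0.05)
        assert clean_fit.converged

    def test_line_self_consistency_on_clean_data(self, clean_fit):
        n = clean_fit.n
        assert clean_fit.line_intercept == pytest.approx((n - 1) / n, rel=0.05)
        assert clean_fit.line_slope == pytest.approx((n - 1) ** 2 / n, rel=0.05)
        assert 0.0 <= clean_fit.r_squared <= 1.0

    def test_k_consistent_with_cmc(self, clean_fit):
        from bilemic.mass_action import MassActionParams, cmc_from_params

        p = MassActionParams(clean_fit.n, clean_fit.K)
        assert cmc_from_params(p) == pytest.approx(clean_fit.cmc, rel=1e-6)

    def test_drop_first_injection_is_benign(self, clean_series, clean_fit):
        alt = fit_demicellization(clean_series, drop_first=True)
        assert abs(alt.n - clean_fit.n) / clean_fit.n < 0.01

    def test_affine_consistency(self, clean_series, clean_fit):
        """Rescaling all heats rescales the enthalpies and nothing else."""
        lam = 3.7
        scaled = ITCInjectionSeries(
            syringe_conc=clean_series.syringe_conc,
            cell_volume=clean_series.cell_volume,
            injection_volumes=clean_series.injection_volumes,
            heats=lam * clean_series.heats,
            temperature=clean_series.temperature,
        )
        res = fit_demicellization(scaled)
        assert res.n == pytest.approx(clean_fit.n, rel=1e-4)
        assert res.cmc == pytest.approx(clean_fit.cmc, rel=1e-4)
        assert res.dH_demic == pytest.approx(lam * clean_fit.dH_demic, rel=1e-4)
        assert res.dH_dil == pytest.approx(lam * clean_fit.dH_dil, rel=1e-4)

    def test_constant_heats_mean_no_transition(self):
        s = _series(np.full(20, -0.3), syringe=4.0)
        with pytest.raises(NoTransitionError):
            fit_demicellization(s)

    def test_too_few_injections_rejected(self):
        s = _series(np.linspace(-5, -0.2, 8), syringe=4.0)
        with pytest.raises(InsufficientDataError):
            fit_demicellization(s)

    def test_deterministic(self, clean_series):
        a = fit_demicellization(clean_series)
        b = fit_demicellization(clean_series)
        assert a.n == b.n and a.cmc == b.cmc and a.dH_demic == b.dH_demic


class TestEstimatorApi:
    def test_fit_predict_round_trip(self, clean_series):
        est = DemicellizationEstimator(syringe_conc=4.0, cell_volume=200.0)
        X = clean_series.injection_volumes.reshape(-1, 1)
        est.fit(X, clean_series.heats)
        assert est.n_ == pytest.approx(TRUTH["n"], rel=0.02)
        pred = est.predict(X)
        assert np.allclose(pred, clean_series.heats, atol=1e-6)

    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = DemicellizationEstimator(syringe_conc=4.0, drop_first=True)
        params = est.get_params()
        assert params["drop_first"] is True
        est2 = clone(est).set_params(drop_first=False)
        assert est2.get_params()["syringe_conc"] == 4.0
        assert est2.get_params()["drop_first"] is False
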