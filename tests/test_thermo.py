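"""State functions, counterion-corrected K_mic, heat capacity and summaries."""

import math

import numpy as np
import pytest

from bilemic.exceptions import ValidationError
from bilemic.thermo import (
    ThermoRecord,
    build_record,
    delta_g_demic,
    delta_s_demic,
    heat_capacity_demic,
    k_mic,
    mole_fraction_from_cmc,
    sodium_term_contribution,
    summarize,
)


class TestKmic:
    def test_no_binding_limit(self):
        assert k_mic(3.2e7, 0.1, 0.0, 12.0) == pytest.approx(3.2e7)

    def test_unit_activity_limit(self):
        assert k_mic(3.2e7, 1.0, 0.6, 12.0) == pytest.approx(3.2e7)

    def test_reference_value(self):
        assert k_mic(1e10, 0.0765, 0.5, 10.0) == pytest.approx(2.62e4, rel=1e-3)

    def test_beta_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            k_mic(1.0, 0.1, 1.2, 10.0)


class TestDeltaG:
    def test_unit_constant_gives_zero(self):
        assert delta_g_demic(1.0, 298.15, 10.0) == 0.0

    def test_reference_value(self):
        assert delta_g_demic(2.62e4, 298.15, 10.0) == pytest.approx(2.52, abs=0.01)

    def test_doubling_n_halves_result(self):
        g1 = delta_g_demic(2.62e4, 298.15, 10.0)
        g2 = delta_g_demic(2.62e4, 298.15, 20.0)
        assert g2 == pytest.approx(g1 / 2.0)


class TestDeltaS:
    @pytest.mark.parametrize(
        "dG,dH,T,expected",
        [
            (27.3, -2.9, 298.15, -101.29),   # NaAdC at 25 degC
            (25.1, -8.2, 283.15, -117.61),   # NaAdC at 10 degC
            (5.0, 5.0, 300.0, 0.0),
        ],
    )
    def test_reference_values(self, dG, dH, T, expected):
        assert delta_s_demic(dG, dH, T) == pytest.approx(expected, abs=0.01)


class TestHeatCapacity:
    def test_closed_form_ols_oracle(self):
        rng = np.random.default_rng(11)
        T = np.linspace(283.0, 318.0, 6)
        H = -9.0 + 0.31 * (T - 283.0) + rng.normal(0, 0.2, 6)
        slope, _ = heat_capacity_demic(list(zip(T, H)))
        oracle = np.sum((T - T.mean()) * (H - H.mean())) / np.sum((T - T.mean()) ** 2)
        assert slope == pytest.approx(1000.0 * oracle, rel=1e-12)

    def test_constant_enthalpy_gives_zero(self):
        slope, _ = heat_capacity_demic([(290.0, 1.5), (300.0, 1.5), (310.0, 1.5)])
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_reference_tables(self, thermo_df):
        grp = thermo_df[thermo_df.surfactant == "NaAdCH2C"]
        slope, _ = heat_capacity_demic(list(zip(grp.T_K, grp.dH_kJ_mol)))
        assert slope == pytest.approx(300.0, rel=0.02)
        grp = thermo_df[thermo_df.surfactant == "NatButPhC"]
        slope, _ = heat_capacity_demic(list(zip(grp.T_K, grp.dH_kJ_mol)))
        assert slope == pytest.approx(462.0, abs=1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            heat_capacity_demic([(290.0, 1.0), (300.0, 2.0)])


class TestMoleFraction:
    @pytest.mark.parametrize(
        "cmc,expected", [(0.323, 5.82e-6), (0.182, 3.28e-6), (0.0, 0.0)]
    )
    def test_reference_values(self, cmc, expected):
        assert mole_fraction_from_cmc(cmc) == pytest.approx(expected, abs=5e-9)


class TestSodiumTerm:
    def test_reference_value_in_printed_band(self):
        v = sodium_term_contribution(0.49, 10.0, 0.0765, 298.15)
        assert v == pytest.approx(3.12, abs=0.01)

    @pytest.mark.parametrize("beta,sodium", [(0.0, 0.1), (0.5, 1.0)])
    def test_vanishing_limits(self, beta, sodium):
        assert sodium_term_contribution(beta, 10.0, sodium, 298.15) == 0.0

    def test_decomposition_consistency(self):
        """dG with sodium minus dG at unit activity equals +/- the sodium term."""
        K, Na, beta, n, T = 3e9, 0.0765, 0.63, 11.0, 298.15
        diff = delta_g_demic(k_mic(K, Na, beta, n), T, n) - delta_g_demic(
            k_mic(K, 1.0, beta, n), T, n
        )
        assert abs(diff) == pytest.approx(
            sodium_term_contribution(beta, n, Na, T), rel=1e-9
        )


class TestSummaries:
    def test_gibbs_helmholtz_exact_by_construction(self):
        rec = build_record(
            temperature=298.15, cmc=0.45, n=10.0, dH_demic=-5.0,
            K=1e9, sodium=0.0765, beta=0.63,
        )
        assert rec.dG_demic == pytest.approx(
            rec.dH_demic - rec.temperature * rec.dS_demic / 1000.0, abs=1e-9
        )

    def test_reference_table_bookkeeping_residual(self, thermo_df):
        """Printed dG/dH/T/dS rows obey dG = dH - T*dS within the propagated
        printing precision (dG, dH to 0.1 kJ/mol; dS to 1 J/(mol K))."""
        resid = (
            thermo_df.dG_kJ_mol
            - (thermo_df.dH_kJ_mol - thermo_df.T_K * thermo_df.dS_J_mol_K / 1000.0)
        ).abs()
        bound = 0.1 + thermo_df.T_K * 0.5 / 1000.0
        assert bool((resid <= bound).all())

    def test_mean_aggregation_numbers(self, thermo_df):
        recs = [
            ThermoRecord(r.T_K, r.cmc_mM, r.x_cmc_e6 * 1e-6, r.n,
                         r.dG_kJ_mol, r.dH_kJ_mol, r.dS_J_mol_K)
            for r in thermo_df[thermo_df.surfactant == "NaAdC"].itertuples()
        ]
        summ = summarize(recs)
        assert summ.mean_n == pytest.approx(6.4875, abs=1e-4)
        assert summ.sd_n == pytest.approx(0.66, abs=0.01)

    def test_identical_records_have_zero_spread(self):
        rec = ThermoRecord(298.15, 0.4, 7e-6, 10.0, 28.0, -3.0, -104.0)
        recs = [rec, rec, rec]
        summ = summarize(recs)
        assert summ.sd_n == 0.0
        assert summ.dCp_demic != summ.dCp_demic or summ.dCp_demic == pytest.approx(0.0)

    def test_summary_dcp_equals_ols_slope(self, thermo_df):
        grp = thermo_df[thermo_df.surfactant == "NaAdCH2C"]
        recs = [
            ThermoRecord(r.T_K, r.cmc_mM, r.x_cmc_e6 * 1e-6, r.n,
                         r.dG_kJ_mol, r.dH_kJ_mol, r.dS_J_mol_K)
            for r in grp.itertuples()
        ]
        summ = summarize(recs)
        slope, stderr = heat_capacity_demic(list(zip(grp.T_K, grp.dH_kJ_mol)))
        assert summ.dCp_demic == slope
        assert summ.dCp_stderr == stderr
        assert math.isfinite(summ.dCp_stderr)
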