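import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stemfit as sf
from stemfit.errors import DomainError
from stemfit.models.closed_forms import BATCH_FUNCS, cole_z, double_cole_z
from stemfit.synth import sample_params

from .conftest import single_freq_grid

RTOL_LIMIT = 1e-4      # relative tolerance at surrogate frequencies
RTOL_ORACLE = 1e-9     # rational form vs admittance oracle

F_LOW = 1e-9
F_HIGH = 1e12


class TestCPE:
    def test_ideal_capacitor(self):
        # 1 uF at omega = 1000 rad/s -> -1000j ohm
        grid = single_freq_grid(159.1549431)
        z = sf.cpe_impedance(sf.CPE(c=1e-6, order=1.0), grid).z[0]
        np.testing.assert_allclose(z, -1000j, rtol=1e-8)

    def test_order_zero_is_resistor(self):
        grid = single_freq_grid(42.0)
        z = sf.cpe_impedance(sf.CPE(c=0.5, order=0.0), grid).z[0]
        assert z == pytest.approx(2.0 + 0.0j)

    def test_half_order_at_unit_omega(self):
        grid = single_freq_grid(1.0 / (2.0 * np.pi))
        z = sf.cpe_impedance(sf.CPE(c=1.0, order=0.5), grid).z[0]
        np.testing.assert_allclose(z, 0.70710678 - 0.70710678j, rtol=1e-8)

    @pytest.mark.parametrize("c,order", [(0.0, 0.5), (-1.0, 0.5),
                                         (1.0, -0.1), (1.0, 1.1)])
    def test_domain_errors(self, c, order):
        with pytest.raises(DomainError):
            sf.CPE(c=c, order=order)

    @given(order=st.floats(0.01, 1.0), log_f=st.floats(-2.0, 8.0),
           log_c=st.floats(-12.0, -3.0))
    @settings(max_examples=100, deadline=None)
    def test_constant_phase_property(self, order, log_f, log_c):
        c = 10.0 ** log_c
        grid = single_freq_grid(10.0 ** log_f)
        z = sf.cpe_impedance(sf.CPE(c=c, order=order), grid).z[0]
        assert np.angle(z) == pytest.approx(-order * np.pi / 2.0, abs=1e-12)
        assert abs(z) == pytest.approx(1.0 / (c * grid.omega[0] ** order),
                                       rel=1e-12)


class TestCole:
    def test_table_preset_matches_oracle_value(self, marjoram5_cole):
        # frozen from the admittance oracle on the series/parallel topology
        grid = single_freq_grid(1000.0)
        z = sf.cole_impedance(marjoram5_cole, grid).z[0]
        np.testing.assert_allclose(
            z, 170290.93469001283 - 35214.43448266569j, rtol=1e-9)

    def test_low_frequency_limit_is_r_o(self, marjoram5_cole):
        z = sf.cole_impedance(marjoram5_cole, single_freq_grid(F_LOW)).z[0]
        assert abs(z - marjoram5_cole["r_o"]) < RTOL_LIMIT * marjoram5_cole["r_o"]

    def test_high_frequency_limit_is_r_inf(self):
        # the relaxation term decays like omega^-alpha, so the surrogate
        # frequency resolves the limit only for a strong enough CPE
        params = sf.make_params("cole", [0.9, 1e4, 1e5, 1e-9])
        z = sf.cole_impedance(params, single_freq_grid(F_HIGH)).z[0]
        np.testing.assert_allclose(z, params["r_inf"], rtol=RTOL_LIMIT)

    def test_debye_case(self):
        # alpha=1, R_inf=0, R_o=100k, C=1nF at omega=1/(R_o C)
        params = sf.make_params("cole", [1.0, 0.0, 1e5, 1e-9])
        grid = single_freq_grid(1e4 / (2.0 * np.pi))
        z = sf.cole_impedance(params, grid).z[0]
        np.testing.assert_allclose(z, 50_000.0 - 50_000.0j, rtol=1e-9)
        z_oracle = sf.oracle_impedance("cole", params, grid).z[0]
        np.testing.assert_allclose(z_oracle, z, rtol=1e-12)

    def test_rejects_r_o_below_r_inf(self):
        params = sf.make_params("cole", [0.5, 5e4, 1e4, 1e-9])
        with pytest.raises(DomainError, match="r_o > r_inf"):
            sf.cole_impedance(params, single_freq_grid(1.0))


class TestDoubleCole:
    def test_table_preset_matches_oracle_value(self):
        params = sf.get_preset("double_cole", "salvia5")
        grid = single_freq_grid(100.0)
        z = sf.double_cole_impedance(params, grid).z[0]
        np.testing.assert_allclose(
            z, 437769.6132187156 - 35968.93634235161j, rtol=1e-9)

    def test_low_frequency_limit(self):
        params = sf.get_preset("double_cole", "salvia5")
        z = sf.double_cole_impedance(params, single_freq_grid(F_LOW)).z[0]
        total = params["r_inf"] + params["r_1"] + params["r_2"]
        np.testing.assert_allclose(z, total, rtol=RTOL_LIMIT)

    def test_reduces_to_cole_without_second_section(self, grid_241):
        # R_2 = 0 removes the beta section; equals cole with R_o = R_inf+R_1
        alpha, r_inf, r1, c_a = 0.7, 1e3, 2e5, 5e-9
        dc = double_cole_z(
            np.array([alpha, 0.9, r_inf, r1, 0.0, c_a, 1e-9]), grid_241.omega)
        cole = cole_z(np.array([alpha, r_inf, r_inf + r1, c_a]),
                      grid_241.omega)
        np.testing.assert_allclose(dc, cole, rtol=1e-12)

    def test_rejects_nonpositive_sections(self):
        params = sf.make_params(
            "double_cole", [0.5, 0.5, 0.0, 0.0, 1e5, 1e-9, 1e-9])
        with pytest.raises(DomainError):
            sf.double_cole_impedance(params, single_freq_grid(1.0))


class TestDoubleShell:
    def test_table_preset_matches_oracle_value(self):
        params = sf.get_preset("double_shell", "marjoram10")
        grid = single_freq_grid(1000.0)
        z = sf.double_shell_impedance(params, grid).z[0]
        np.testing.assert_allclose(
            z, 603291.6249327094 - 272467.9724465954j, rtol=1e-9)

    def test_low_frequency_limit_is_r_1(self):
        params = sf.get_preset("double_shell", "marjoram10")
        z = sf.double_shell_impedance(params, single_freq_grid(F_LOW)).z[0]
        np.testing.assert_allclose(z, params["r_1"], rtol=RTOL_LIMIT)

    def test_high_frequency_limit_is_three_resistor_parallel(self):
        params = sf.get_preset("double_shell", "marjoram10")
        r1, r2, r3 = params["r_1"], params["r_2"], params["r_3"]
        expected = r1 * r2 * r3 / (r2 * r3 + r1 * r2 + r1 * r3)
        z = sf.double_shell_impedance(params, single_freq_grid(F_HIGH)).z[0]
        np.testing.assert_allclose(z, expected, rtol=RTOL_LIMIT)


class TestStem:
    def test_open_branches_leave_bare_resistor(self, grid_241):
        # all five capacitances zero: only the outer resistor conducts
        spec = sf.get_spec("stem")
        values = np.zeros(15)
        values[spec.index("r_o")] = 12_345.0
        values[[spec.index(n) for n in
                ("alpha", "beta", "gamma", "zeta", "lambda")]] = 0.5
        values[[spec.index(n) for n in ("r_1", "r_2", "r_3", "r_4")]] = 1e6
        params = sf.ParameterVector(spec, values)
        z = sf.oracle_impedance("stem", params, grid_241).z
        np.testing.assert_allclose(z, 12_345.0 + 0j, rtol=1e-12)

    def test_high_frequency_magnitude_vanishes(self):
        params = sample_params("stem", seed=3)
        z = sf.stem_impedance(params, single_freq_grid(F_HIGH)).z[0]
        assert abs(z) < 1e-3 * params["r_o"]

    def test_low_frequency_limit_is_r_o(self):
        # every CPE-bearing branch blocks DC; holds at the surrogate
        # frequency when 1/(omega^order * C) >> R_o for all branches
        values = np.array([0.6, 0.6, 0.6, 0.6, 0.6,
                           1e5, 1e4, 1e4, 1e4, 1e4,
                           1e-8, 1e-8, 1e-8, 1e-8, 1e-8])
        params = sf.ParameterVector(sf.get_spec("stem"), values)
        z = sf.stem_impedance(params, single_freq_grid(F_LOW)).z[0]
        np.testing.assert_allclose(z, params["r_o"], rtol=RTOL_LIMIT)

    def test_rejects_nonpositive_r_o(self):
        spec = sf.get_spec("stem")
        values = np.full(15, 0.5)
        values[5:10] = [0.0, 1e3, 1e3, 1e3, 1e3]
        values[10:] = 1e-9
        params = sf.ParameterVector(spec, values)
        with pytest.raises(DomainError, match="r_o"):
            sf.stem_impedance(params, single_freq_grid(1.0))


class TestSimplifiedStem:
    def test_high_frequency_limit_is_r_o(self):
        params = sample_params("simplified_stem", seed=5)
        z = sf.simplified_stem_impedance(
            params, single_freq_grid(F_HIGH)).z[0]
        np.testing.assert_allclose(z, params["r_o"], rtol=RTOL_LIMIT)

    def test_integer_order_matches_nodal_analysis(self):
        # alpha=beta=gamma=1 against a hand-rolled ideal-capacitor circuit
        r_o, r1, r2, c = 1e3, 1e4, 1e4, 1e-9
        params = sf.make_params(
            "simplified_stem", [1.0, 1.0, 1.0, r_o, r1, r2, c, c, c])
        grid = sf.make_grid(100.0, 100_000.0, 10)
        z = sf.simplified_stem_impedance(params, grid).z
        jwc = 1j * grid.omega * c
        y = 1.0 / (r1 + 1.0 / jwc) + 1.0 / (r2 + 1.0 / jwc) + jwc
        np.testing.assert_allclose(z, r_o + 1.0 / y, rtol=1e-12)

    def test_rejects_zero_capacitance(self):
        params = sf.make_params(
            "simplified_stem", [0.5, 0.5, 0.5, 1e3, 1e4, 1e4, 1e-9, 0.0, 1e-9])
        with pytest.raises(DomainError):
            sf.simplified_stem_impedance(params, single_freq_grid(1.0))


class TestOracle:
    @pytest.mark.parametrize("model_id", sf.MODEL_IDS)
    def test_rational_form_matches_topology(self, model_id, grid_241):
        for k in range(20):
            params = sample_params(model_id, seed=900 + k)
            z_rat = sf.model_impedance(model_id, params, grid_241).z
            z_orc = sf.oracle_impedance(model_id, params, grid_241).z
            dev = np.max(np.abs(z_rat - z_orc) / np.abs(z_orc))
            assert dev < RTOL_ORACLE

    def test_mismatched_params_rejected(self, marjoram5_cole, grid_241):
        topo = sf.topology_for("stem")
        with pytest.raises(DomainError):
            sf.circuit_oracle_impedance(topo, marjoram5_cole, grid_241)

    def test_unknown_model_rejected(self):
        with pytest.raises(DomainError):
            sf.topology_for("hayden")


class TestProperties:
    @pytest.mark.parametrize("model_id", sf.MODEL_IDS)
    def test_passivity(self, model_id, grid_241):
        for k in range(20):
            params = sample_params(model_id, seed=700 + k)
            z = sf.model_impedance(model_id, params, grid_241).z
            assert np.all(z.real > 0.0)
            assert np.all(z.imag <= 0.0)

    @pytest.mark.parametrize("model_id", ["cole", "double_cole"])
    def test_magnitude_non_increasing(self, model_id, grid_241):
        for k in range(20):
            params = sample_params(model_id, seed=800 + k)
            mag = np.abs(sf.model_impedance(model_id, params, grid_241).z)
            assert np.all(np.diff(mag) <= mag[:-1] * 1e-12)

    def test_simplified_stem_differs_from_stem(self, grid_241):
        # the two proposed topologies are genuinely different circuits
        ss = sf.make_params(
            "simplified_stem",
            [0.8, 0.7, 0.9, 1e3, 1e5, 2e5, 1e-8, 2e-8, 1e-9])
        stem_vals = np.array([0.8, 0.7, 0.9, 0.9, 0.9, 1e3, 1e5, 2e5,
                              1e5, 1e5, 1e-8, 2e-8, 1e-9, 1e-9, 1e-9])
        stem = sf.ParameterVector(sf.get_spec("stem"), stem_vals)
        z_ss = sf.simplified_stem_impedance(ss, grid_241).z
        z_stem = sf.stem_impedance(stem, grid_241).z
        assert np.max(np.abs(z_ss - z_stem) / np.abs(z_stem)) > 0.01


class TestBatchEvaluators:
    @pytest.mark.parametrize("model_id", sf.MODEL_IDS)
    def test_batch_rows_match_single_eval(self, model_id, grid_241, rng):
        rows = np.stack([sample_params(model_id, seed=60 + k).values
                         for k in range(5)])
        z_batch = BATCH_FUNCS[model_id](rows, grid_241.omega)
        for k in range(5):
            z_one = BATCH_FUNCS[model_id](rows[k], grid_241.omega)[0]
            np.testing.assert_array_equal(z_batch[k], z_one)
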