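"""Single-site ITC forward model and nonlinear fitting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pepbiophys as pb


class TestPostInjectionConcentrations:
    def test_index_out_of_range(self, itc_design):
        with pytest.raises(IndexError):
            pb.post_injection_concentrations(itc_design, 0)
        with pytest.raises(IndexError):
            pb.post_injection_concentrations(itc_design, 20)

    def test_small_injection_limit(self):
        exp = pb.ITCExperiment(
            cell_volume=200.0, titrand_conc0=20.0, titrant_conc_syringe=200.0,
            injection_volumes=[1e-9],
        )
        m, x = pb.post_injection_concentrations(exp, 1)
        assert m == pytest.approx(20.0, rel=1e-8)
        assert x == pytest.approx(0.0, abs=1e-9)

    def test_hand_evaluated_last_injection(self, itc_design):
        # v = 38 µL, V0 = 200 µL: r = 38/400 = 0.095
        m, x = pb.post_injection_concentrations(itc_design, 19)
        assert m == pytest.approx(20.0 * (1 - 0.095) / (1 + 0.095), rel=1e-12)
        assert x == pytest.approx(200.0 * (38.0 / 200.0) / (1 + 0.095), rel=1e-12)

    def test_monotone_in_injection_index(self, itc_design):
        pairs = [pb.post_injection_concentrations(itc_design, i) for i in range(1, 20)]
        titrand = [p[0] for p in pairs]
        titrant = [p[1] for p in pairs]
        assert np.all(np.diff(titrand) < 0)
        assert np.all(np.diff(titrant) > 0)


class TestBoundConcentration:
    def test_no_titrant(self):
        assert pb.bound_concentration(10.0, 0.0, 1.0) == 0.0

    def test_tight_binding_limit(self):
        assert pb.bound_concentration(10.0, 4.0, 1e-9) == pytest.approx(4.0, rel=1e-6)
        assert pb.bound_concentration(3.0, 8.0, 1e-9) == pytest.approx(3.0, rel=1e-6)

    def test_symmetric_closed_form(self):
        kd = 2.5
        assert pb.bound_concentration(kd, kd, kd, n=1.0) == pytest.approx(
            (3 - math.sqrt(5)) / 2 * kd
        )

    @given(
        m=st.floats(0.1, 100), x=st.floats(0, 300),
        kd=st.floats(1e-3, 1e3), n=st.floats(0.5, 2),
    )
    def test_bounds_and_monotonicity(self, m, x, kd, n):
        mx = pb.bound_concentration(m, x, kd, n)
        assert -1e-12 <= mx <= min(n * m, x) + 1e-9
        assert pb.bound_concentration(m, x + 1.0, kd, n) >= mx - 1e-12
        assert pb.bound_concentration(m, x, kd * 2, n) <= mx + 1e-12


class TestInjectionHeats:
    def test_zero_enthalpy_zero_heats(self, itc_design):
        heats = pb.injection_heats(itc_design, kd=1.0, dh=0.0, q_dil=0.0)
        assert np.allclose(heats, 0.0)

    def test_tight_binding_plateau_equals_dh(self, itc_design):
        """Early titrant-normalized heats approach ΔH when binding is
        stoichiometric (Kd << cell concentration)."""
        heats = pb.injection_heats(itc_design, kd=1e-4, dh=1.3)
        norm = pb.normalized_heats(itc_design, heats)
        assert norm[0] == pytest.approx(1.3, rel=0.02)
        assert norm[1] == pytest.approx(1.3, rel=0.02)

    def test_conservation_against_stepwise_oracle(self, itc_design):
        """Sum of per-injection heats matches an independent step-by-step
        mass-balance accumulation."""
        kd, dh, n = 1.4, 1.3, 1.0
        heats = pb.injection_heats(itc_design, kd, dh, n, q_dil=0.0)

        # independent oracle: accumulate Q_i from scratch
        v0 = itc_design.cell_volume
        vols = itc_design.injection_volumes
        total = 0.0
        q_prev = 0.0
        v_cum = 0.0
        for dv in vols:
            v_cum += dv
            r = v_cum / (2 * v0)
            m_i = itc_design.titrand_conc0 * (1 - r) / (1 + r)
            x_i = itc_design.titrant_conc_syringe * (v_cum / v0) / (1 + r)
            b = n * m_i + x_i + kd
            mx = 0.5 * (b - math.sqrt(b * b - 4 * n * m_i * x_i))
            q_i = dh * v0 * mx * 1e-3
            total += q_i - q_prev + (dv / v0) * (q_i + q_prev) / 2
            q_prev = q_i
        assert float(np.sum(heats)) == pytest.approx(total, rel=1e-12)

    @given(dh=st.floats(-10, 10))
    def test_linear_in_enthalpy(self, itc_design, dh):
        base = pb.injection_heats(itc_design, kd=2.0, dh=1.0)
        scaled = pb.injection_heats(itc_design, kd=2.0, dh=dh)
        assert np.allclose(scaled, dh * base, atol=1e-12)

    def test_sign_flip_negates_heats(self, itc_design):
        up = pb.injection_heats(itc_design, kd=1.4, dh=1.3)
        down = pb.injection_heats(itc_design, kd=1.4, dh=-1.3)
        assert np.allclose(up, -down)


class TestFitItc:
    def test_noiseless_exact_recovery(self, itc_design):
        heats = pb.gen_itc(1.4, 1.3)
        fit = pb.fit_itc(itc_design, heats)
        assert fit.kd == pytest.approx(1.4, rel=1e-6)
        assert fit.dh == pytest.approx(1.3, rel=1e-6)
        assert fit.n == pytest.approx(1.0, rel=1e-6)
        assert fit.identifiable

    def test_noisy_recovery(self, itc_design):
        heats = pb.gen_itc(1.4, 1.3, noise=pb.NoiseSpec(sigma=0.02, seed=0))
        fit = pb.fit_itc(itc_design, heats)
        assert fit.kd == pytest.approx(1.4, rel=0.25)
        assert fit.dh == pytest.approx(1.3, rel=0.15)

    def test_fixed_stoichiometry_mode(self, itc_design):
        heats = pb.gen_itc(1.4, 1.3, noise=pb.NoiseSpec(sigma=0.02, seed=4))
        fit = pb.fit_itc(itc_design, heats, fix_n=True)
        assert fit.n == 1.0
        assert fit.kd == pytest.approx(1.4, rel=0.25)

    def test_low_c_value_flagged(self, itc_design):
        """Kd = 500 µM at a 20 µM cell gives c ≈ 0.04: the isotherm shape
        cannot determine Kd."""
        heats = pb.gen_itc(500.0, 1.3, noise=pb.NoiseSpec(sigma=0.02, seed=3))
        fit = pb.fit_itc(itc_design, heats)
        assert not fit.identifiable

    def test_unit_coherence(self, itc_design):
        """Rescaling heats µcal → cal rescales ΔH and q_dil but not Kd."""
        heats = pb.gen_itc(1.4, 1.3, q_dil=0.05, noise=pb.NoiseSpec(sigma=0.02, seed=5))
        f1 = pb.fit_itc(itc_design, heats)
        f2 = pb.fit_itc(itc_design, heats * 1e-6)
        assert f2.kd == pytest.approx(f1.kd, rel=1e-5)
        assert f2.dh * 1e6 == pytest.approx(f1.dh, rel=1e-5)
        assert f2.q_dil * 1e6 == pytest.approx(f1.q_dil, rel=1e-4)

    def test_discard_first_makes_fit_insensitive_to_first_heat(self, itc_design):
        heats = pb.gen_itc(1.4, 1.3, noise=pb.NoiseSpec(sigma=0.02, seed=6))
        corrupted = heats.copy()
        corrupted[0] *= 0.2  # typical first-injection artefact
        clean_fit = pb.fit_itc(itc_design, heats, discard_first=True)
        corrupt_fit = pb.fit_itc(itc_design, corrupted, discard_first=True)
        assert corrupt_fit.kd == pytest.approx(clean_fit.kd, rel=1e-9)
        assert corrupt_fit.dh == pytest.approx(clean_fit.dh, rel=1e-9)
        # without the flag the artefact does shift the result
        assert pb.fit_itc(itc_design, corrupted).kd != pytest.approx(clean_fit.kd, rel=1e-6)

    def test_too_few_injections_rejected(self):
        exp = pb.default_itc_experiment(n_injections=5)
        with pytest.raises(ValueError, match="at least 8"):
            pb.fit_itc(exp, np.zeros(5))

    def test_nonfinite_heats_rejected(self, itc_design):
        heats = pb.gen_itc(1.4, 1.3)
        heats[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            pb.fit_itc(itc_design, heats)


class TestExperimentValidation:
    def test_overfilled_cell_rejected(self):
        with pytest.raises(ValueError, match="below the cell volume"):
            pb.ITCExperiment(
                cell_volume=30.0, titrand_conc0=20.0, titrant_conc_syringe=200.0,
                injection_volumes=np.full(19, 2.0),
            )
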