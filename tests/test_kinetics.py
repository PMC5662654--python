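"""Gene-expression rate laws: Hill transfer, promoter logic, kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atranet.kinetics import (
    constitutive_rate,
    expression_rhs,
    hill_transfer,
    promoter_control,
    transcription_kinetic_limit,
    translation_rate,
)
from atranet.network import (
    GeneRecord,
    GlobalParameters,
    NetworkModel,
    RegulatoryInteraction,
)
from atranet.simulate import ModelArrays


def _gene(name="A", w0=0.0, **kw):
    defaults = dict(gene_length_nt=44_192, transcript_length_nt=1_374,
                    protein_length_aa=300, module="integration", basal_weight=w0)
    defaults.update(kw)
    return GeneRecord(name=name, **defaults)


class TestHillTransfer:
    def test_zero_input_is_zero(self):
        assert hill_transfer(0.0, 10.0, 2.0) == 0.0

    @pytest.mark.parametrize("eta", [0.5, 1.0, 2.0, 4.0])
    def test_midpoint_is_half_for_any_cooperativity(self, eta):
        assert hill_transfer(10.0, 10.0, eta) == pytest.approx(0.5)

    def test_twice_k_with_eta_two(self):
        assert hill_transfer(20.0, 10.0, 2.0) == pytest.approx(0.8)

    def test_negative_input_raises(self):
        with pytest.raises(ValueError):
            hill_transfer(-1.0, 10.0, 2.0)

    @given(x=st.floats(0.0, 1e6), k=st.floats(0.01, 1000.0),
           eta=st.floats(0.1, 4.0))
    @settings(max_examples=200, deadline=None)
    def test_bounded_in_unit_interval(self, x, k, eta):
        f = hill_transfer(x, k, eta)
        assert 0.0 <= f <= 1.0

    @given(k=st.floats(0.01, 1000.0), eta=st.floats(0.1, 4.0),
           x1=st.floats(0.0, 1e5), x2=st.floats(0.0, 1e5))
    @settings(max_examples=200, deadline=None)
    def test_monotone_nondecreasing(self, k, eta, x1, x2):
        lo, hi = sorted((x1, x2))
        assert hill_transfer(lo, k, eta) <= hill_transfer(hi, k, eta) + 1e-15


def _two_gene_model(w0=0.1, weight=10.0, sign="activation", K=10.0, eta=1.0):
    genes = [_gene("A", w0=w0), _gene("B")]
    edge = RegulatoryInteraction("B", "A", sign, weight, K, eta)
    return NetworkModel(genes=genes, interactions=[edge]).validate()


class TestPromoterControl:
    def test_unregulated_gene_is_constitutive(self):
        m = NetworkModel(genes=[_gene("A", w0=0.5)], interactions=[]).validate()
        assert promoter_control("A", {}, m).value == 1.0

    def test_single_activator_example(self):
        # W_R1 = 0.1, one activator with W = 10 at f = 0.5 -> 5.1/6.1
        m = _two_gene_model(w0=0.1, weight=10.0, K=10.0, eta=1.0)
        u = promoter_control("A", {"B": 10.0}, m).value
        assert u == pytest.approx(5.1 / 6.1, rel=1e-12)

    def test_single_repressor_example(self):
        # W_R1 = 1, one repressor with W = 10 at f = 1 -> 1/12
        m = _two_gene_model(w0=1.0, weight=10.0, sign="repression", K=1e-2, eta=4.0)
        u = promoter_control("A", {"B": 1e6}, m).value
        assert u == pytest.approx(1.0 / 12.0, rel=1e-3)

    def test_missing_regulator_level_raises(self):
        m = _two_gene_model()
        with pytest.raises(KeyError, match="B"):
            promoter_control("A", {}, m)

    @given(w0=st.floats(0.0, 100.0), w=st.floats(0.0, 100.0),
           level=st.floats(0.0, 1e5),
           sign=st.sampled_from(["activation", "repression"]))
    @settings(max_examples=150, deadline=None)
    def test_control_term_in_unit_interval(self, w0, w, level, sign):
        m = _two_gene_model(w0=w0, weight=w, sign=sign)
        u = promoter_control("A", {"B": level}, m).value
        assert 0.0 <= u <= 1.0

    @given(lo=st.floats(0.0, 1e4), delta=st.floats(0.0, 1e4))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_activator_level(self, lo, delta):
        m = _two_gene_model(weight=20.0, K=50.0, eta=2.0)
        u1 = promoter_control("A", {"B": lo}, m).value
        u2 = promoter_control("A", {"B": lo + delta}, m).value
        assert u2 >= u1 - 1e-12

    @given(lo=st.floats(0.0, 1e4), delta=st.floats(0.0, 1e4))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_repressor_level(self, lo, delta):
        m = _two_gene_model(weight=20.0, sign="repression", K=50.0, eta=2.0)
        u1 = promoter_control("A", {"B": lo}, m).value
        u2 = promoter_control("A", {"B": lo + delta}, m).value
        assert u2 <= u1 + 1e-12


class TestKineticLimits:
    def test_knocked_out_gene_transcribes_nothing(self):
        g = _gene(gene_copies=0.0)
        assert transcription_kinetic_limit(g, GlobalParameters()) == 0.0

    def test_characteristic_transcription_rate_example(self):
        # 1.44 * 85000 * 1 * 2/95002 by hand
        g = _gene()  # L ratio = 1, two copies
        r = transcription_kinetic_limit(g, GlobalParameters())
        assert r == pytest.approx(122_400.0 * 2.0 / 95_002.0, rel=1e-12)
        assert r == pytest.approx(2.577, abs=5e-4)

    def test_doubling_gene_length_halves_rate(self):
        p = GlobalParameters()
        r1 = transcription_kinetic_limit(_gene(), p)
        r2 = transcription_kinetic_limit(_gene(gene_length_nt=2 * 44_192), p)
        assert r2 == pytest.approx(r1 / 2.0)

    def test_constitutive_rate_examples(self):
        p = GlobalParameters()
        assert constitutive_rate(_gene(w0=0.0), p) == 0.0
        r_bar = transcription_kinetic_limit(_gene(), p)
        assert constitutive_rate(_gene(w0=1.0), p) == pytest.approx(r_bar / 2.0)
        # saturation limit W_R1 -> infinity
        assert constitutive_rate(_gene(w0=1e12), p) == pytest.approx(r_bar, rel=1e-9)

    def test_translation_rate_examples(self):
        p = GlobalParameters()
        g = _gene()
        assert translation_rate(g, 0.0, p) == 0.0
        # m = K_X -> half of V_X^max = 3.6e6 -> 1.8e6 copies/hr
        assert translation_rate(g, p.K_X, p) == pytest.approx(1.8e6)
        # saturation limit
        assert translation_rate(g, 1e12, p) == pytest.approx(3.6e6, rel=1e-6)

    def test_negative_mrna_raises(self):
        with pytest.raises(ValueError):
            translation_rate(_gene(), -1.0, GlobalParameters())


class TestExpressionRHS:
    def test_algebraic_steady_state_has_zero_derivative(self):
        m = NetworkModel(genes=[_gene("A", w0=0.5)], interactions=[]).validate()
        p = m.parameters
        r_bar = transcription_kinetic_limit(m.genes[0], p)
        lam = constitutive_rate(m.genes[0], p)
        m_star = (r_bar + lam) / (p.mu + p.theta_m)
        p_star = translation_rate(m.genes[0], m_star, p) / (p.mu + p.theta_p)
        d = expression_rhs({"A_mRNA": m_star, "A_protein": p_star}, m, {})
        assert np.allclose(d, 0.0, atol=1e-9)

    def test_pure_decay_matches_closed_form(self):
        # all weights 0, lambda = 0: m(t) = m0 exp(-(mu+theta_m) t)
        g = _gene("A", w0=0.0, gene_copies=0.0)
        m = NetworkModel(genes=[g], interactions=[]).validate()
        p = m.parameters
        from scipy.integrate import solve_ivp
        sol = solve_ivp(lambda t, y: expression_rhs(y, m, {}),
                        (0.0, 10.0), [5.0, 0.0], rtol=1e-10, atol=1e-12)
        expected = 5.0 * np.exp(-(p.mu + p.theta_m) * sol.t[-1])
        assert sol.y[0, -1] == pytest.approx(expected, rel=1e-6)

    def test_rhs_matches_finite_difference_of_integration(self, model, baseline):
        # oracle: numerical differentiation of the integrator output
        arrays = ModelArrays(model)
        y0 = baseline * 1.07  # off steady state
        from scipy.integrate import solve_ivp
        h = 1e-4
        sol = solve_ivp(arrays.rhs_pss, (0.0, 2 * h), y0, args=(1.0, 0.0),
                        t_eval=[0.0, 2 * h], rtol=1e-12, atol=1e-12,
                        method="LSODA")
        fd = (sol.y[:, 1] - sol.y[:, 0]) / (2 * h)
        mid = 0.5 * (sol.y[:, 1] + sol.y[:, 0])
        rhs = arrays.rhs_pss(h, mid, 1.0, 0.0)
        assert np.allclose(fd, rhs, rtol=1e-4, atol=1e-6)

    def test_nan_state_raises(self, model):
        state = {name: 1.0 for name in model.state_index}
        state["PU1_mRNA"] = np.nan
        signals = {"Trigger_active": 0.0, "signalsome": 0.0, "cRaf_pS621": 0.0}
        with pytest.raises(ValueError, match="NaN"):
            expression_rhs(state, model, signals)

    def test_flow_preserves_non_negativity(self, model):
        arrays = ModelArrays(model)
        rng = np.random.default_rng(5)
        from scipy.integrate import solve_ivp
        for _ in range(3):
            y0 = rng.uniform(0.0, 10.0, 2 * arrays.G)
            sol = solve_ivp(arrays.rhs_pss, (0.0, 50.0), y0, args=(1.0, 0.0),
                            method="LSODA", rtol=1e-8, atol=1e-10)
            assert sol.y.min() >= -1e-9

    def test_frozen_signal_steady_state_matches_long_integration(self, model):
        # steady-state mRNA (rT u + lam)/(mu + theta_m) vs t -> 400 hr flow
        arrays = ModelArrays(model)
        sig = np.array([5.0, 50.0, 500.0])
        from scipy.integrate import solve_ivp

        def rhs_frozen(t, y):
            G = arrays.G
            m = np.maximum(y[:G], 0.0)
            prot = np.maximum(y[G:], 0.0)
            levels = np.concatenate([prot * arrays.nM_per_copy, sig])
            u = arrays.control_terms(levels)
            dm = arrays.rT_bar * u + arrays.lam - arrays.decay_m * m
            dp = arrays.vX * m / (arrays.params.K_X + m) - arrays.decay_p * prot
            return np.concatenate([dm, dp])

        sol = solve_ivp(rhs_frozen, (0.0, 800.0), np.full(2 * arrays.G, 1e-3),
                        method="LSODA", rtol=1e-10, atol=1e-12)
        y = sol.y[:, -1]
        levels = np.concatenate([y[arrays.G:] * arrays.nM_per_copy, sig])
        u = arrays.control_terms(levels)
        m_star = (arrays.rT_bar * u + arrays.lam) / arrays.decay_m
        assert np.allclose(y[:arrays.G], m_star, rtol=1e-3)
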