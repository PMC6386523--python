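"""Per-cell kinetics: Hill responses, reaction terms, bistability and
excitability of the model hierarchy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from pnwave.model_core import (CellFields, HillSpec, ModelParams, Variant,
                               hill, hill_deriv, kinetic_roots_E, reaction_E,
                               reaction_EL, reaction_integrated,
                               upper_stable_root)


class TestHill:
    @pytest.mark.parametrize("x,spec,expected", [
        (0.0, HillSpec(3, 1.0), 0.0),
        (1.0, HillSpec(3, 1.0), 0.5),
        (2.0, HillSpec(3, 1.0), 8.0 / 9.0),
        (0.5, HillSpec(2, 0.5), 0.5),          # half-activation at threshold
        (3.0, HillSpec(1, 3.0), 0.5),
    ])
    def test_values(self, x, spec, expected):
        assert hill(x, spec) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0.0, 50.0), st.floats(0.01, 40.0))
    @settings(max_examples=60, deadline=None)
    def test_bounded_and_halfway_at_threshold(self, x, a):
        spec = HillSpec(exponent=3.0, threshold=a)
        h = hill(x, spec)
        assert 0.0 <= h < 1.0
        assert hill(a, spec) == pytest.approx(0.5)

    def test_strictly_increasing(self):
        xs = np.linspace(0, 10, 500)
        hs = hill(xs, HillSpec(3, 1.2))
        assert np.all(np.diff(hs) > 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            hill(-0.1, HillSpec())

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            HillSpec(exponent=0.0)
        with pytest.raises(ValueError):
            HillSpec(threshold=-1.0)

    def test_derivative_matches_finite_differences(self):
        spec = HillSpec(3, 0.7)
        xs = np.linspace(0.05, 5, 40)
        eps = 1e-6
        fd = (hill(xs + eps, spec) - hill(xs - eps, spec)) / (2 * eps)
        assert np.allclose(hill_deriv(xs, spec), fd, atol=1e-6)


class TestReactionE:
    def test_zero_state_is_fixed_point(self, fig2a):
        assert reaction_E(CellFields(phi_E=0.0), fig2a) == 0.0

    def test_half_activation_value(self, fig2a):
        # mu*h(1) - k*1 = 4*0.5 - 1
        assert reaction_E(CellFields(phi_E=1.0), fig2a) == pytest.approx(1.0)

    def test_wrong_variant_rejected(self, fig2b):
        with pytest.raises(ValueError):
            reaction_E(CellFields(phi_E=1.0), fig2b)

    def test_roots_match_polynomial_oracle(self, fig2a):
        """Non-zero roots of mu*x^3/(1+x^3) = x solve x^3 - mu*x^2 + 1 = 0;
        numpy's companion-matrix roots are the independent oracle."""
        roots = kinetic_roots_E(fig2a)
        poly = np.roots([1.0, -fig2a.mu_E / fig2a.k_E, 0.0, 1.0])
        oracle = sorted([0.0] + [float(r.real) for r in poly
                                 if abs(r.imag) < 1e-12 and r.real > 0])
        assert len(roots) == 3
        assert np.allclose(roots, oracle, atol=1e-9)

    def test_bistability_stability_pattern(self, fig2a):
        """Outer roots attract, the middle root repels (rate-derivative signs)."""
        roots = kinetic_roots_E(fig2a)
        eps = 1e-6

        def f(x):
            return float(reaction_E(CellFields(phi_E=x), fig2a))

        lo, mid, hi = roots
        assert (f(mid + eps) - f(mid - eps)) > 0          # unstable
        assert (f(lo + eps) - f(max(lo - eps, 0.0))) <= 0  # stable at 0
        assert (f(hi + eps) - f(hi - eps)) < 0             # stable

    def test_upper_stable_root_value(self, fig2a):
        assert upper_stable_root(fig2a) == pytest.approx(3.9354323, abs=1e-6)


class TestReactionEL:
    def test_origin_fixed_point(self, fig2b):
        assert reaction_EL(CellFields(), fig2b) == (0.0, 0.0)

    def test_reference_point(self, fig2b):
        dE, dL = reaction_EL(CellFields(phi_E=1.0, phi_L=0.0), fig2b)
        assert dE == pytest.approx(1.0)   # 4*0.5*(1-0) - 1*1
        assert dL == pytest.approx(0.2)   # 0.4*0.5 - 0.2*0

    def test_large_L_suppresses_gain(self, fig2b):
        dE, _ = reaction_EL(CellFields(phi_E=2.0, phi_L=1e6), fig2b)
        assert dE == pytest.approx(-fig2b.k_E * 2.0, rel=1e-6)

    def test_excitable_pulse_in_space_free_system(self, fig2b):
        """A super-threshold kick produces a transient excursion that returns
        to the quiescent state; the origin is the only homogeneous attractor."""
        def rhs(t, y):
            dE, dL = reaction_EL(CellFields(phi_E=max(y[0], 0), phi_L=max(y[1], 0)),
                                 fig2b)
            return [dE, dL]

        sol = solve_ivp(rhs, (0, 200), [1.5, 0.0], rtol=1e-8, dense_output=True)
        peak = sol.y[0].max()
        assert peak > 2.0                       # large excursion
        assert sol.y[0][-1] < 1e-3              # E back to rest
        assert sol.y[1][-1] < 1e-2              # L decays toward 0
        # sub-threshold perturbations decay without an excursion
        sol2 = solve_ivp(rhs, (0, 50), [0.3, 0.0], rtol=1e-8)
        assert sol2.y[0].max() < 0.5


class TestReactionIntegrated:
    def test_origin_fixed_point_without_basal_production(self, fig3):
        p = fig3.with_updates(beta=0.0, basal_D=0.0)
        rates = reaction_integrated(CellFields(), 0.0, p)
        assert all(abs(float(r)) == 0.0 for r in rates)

    def test_basal_notch_only(self, fig3):
        p = fig3.with_updates(basal_D=0.0)
        dE, dL, dD, dN, dOm = reaction_integrated(CellFields(), 0.0, p)
        assert float(dN) == pytest.approx(p.beta)
        assert float(dE) == float(dL) == float(dD) == float(dOm) == 0.0

    def test_negative_neighbor_delta_rejected(self, fig3):
        with pytest.raises(ValueError):
            reaction_integrated(CellFields(), -0.5, fig3)

    def test_wrong_variant_rejected(self, fig2a):
        with pytest.raises(ValueError):
            reaction_integrated(CellFields(), 0.0, fig2a)

    def test_homogeneous_steady_state_is_rate_root(self, fig3):
        """The neuroepithelial resting state found by damped fixed-point
        iteration is verified as a root of the space-free rate function by an
        independent multidimensional root-finder."""
        def space_free(v):
            E, L, D, N = np.maximum(v, 0.0)
            rates = reaction_integrated(
                CellFields(phi_E=E, phi_L=L, phi_D=D, phi_N=N, omega=0.0),
                D, fig3)
            return [float(r) for r in rates[:4]]

        x = np.array([0.1, 0.0, 0.1, 5.0])
        for _ in range(4000):
            x = np.maximum(x + 0.02 * np.array(space_free(x)), 0.0)
        root = fsolve(space_free, x, full_output=False)
        assert np.allclose(space_free(root), 0.0, atol=1e-9)
        assert np.allclose(x, root, atol=1e-4)
        assert root[3] > 1.0  # basal Notch plateau

    def test_omega_rate_is_irreversible(self, fig3, rng):
        for _ in range(50):
            f = CellFields(phi_E=rng.uniform(0, 8), phi_L=rng.uniform(0, 2),
                           phi_D=rng.uniform(0, 4), phi_N=rng.uniform(0, 10),
                           omega=rng.uniform(0, 1))
            *_, dOm = reaction_integrated(f, rng.uniform(0, 4), fig3)
            assert float(dOm) >= 0.0

    def test_rates_cannot_push_fields_negative(self, fig3, rng):
        """At zero value of any field, that field's rate is non-negative."""
        for _ in range(50):
            base = dict(phi_E=rng.uniform(0, 8), phi_L=rng.uniform(0, 2),
                        phi_D=rng.uniform(0, 4), phi_N=rng.uniform(0, 10),
                        omega=rng.uniform(0, 0.9))
            for i, name in enumerate(["phi_E", "phi_L", "phi_D", "phi_N"]):
                f = CellFields(**{**base, name: 0.0})
                rates = reaction_integrated(f, rng.uniform(0, 4), fig3)
                assert float(rates[i]) >= 0.0

    def test_jacobian_sign_structure(self, fig3):
        """Each regulatory arrow's partial derivative has its stated sign at
        a generic positive state."""
        state = dict(phi_E=1.0, phi_L=0.4, phi_D=0.8, phi_N=2.0, omega=0.2)
        nbD = 0.6
        eps = 1e-6

        def partial(idx, name):
            if name == "nbD":
                up = reaction_integrated(CellFields(**state), nbD + eps, fig3)[idx]
                dn = reaction_integrated(CellFields(**state), nbD - eps, fig3)[idx]
            else:
                up = reaction_integrated(
                    CellFields(**{**state, name: state[name] + eps}), nbD, fig3)[idx]
                dn = reaction_integrated(
                    CellFields(**{**state, name: state[name] - eps}), nbD, fig3)[idx]
            return float(up - dn) / (2 * eps)

        iE, iL, iD, iN = 0, 1, 2, 3
        assert partial(iE, "phi_L") < 0       # L shuts down E gain
        assert partial(iE, "phi_N") > 0       # Notch reinforces EGFR
        assert partial(iL, "phi_E") > 0       # EGFR activates L'sc
        assert partial(iL, "phi_N") < 0       # Notch represses L'sc
        assert partial(iD, "phi_E") > 0       # EGFR upregulates Delta
        assert partial(iD, "phi_N") < 0       # Notch represses Delta
        assert partial(iN, "nbD") > 0         # trans-activation
        assert partial(iN, "phi_D") < 0       # cis-inhibition
        assert partial(iN, "phi_L") < 0       # L'sc represses Notch

    def test_decay_limit_closed_form(self, fig3):
        """With all gains off, every field decays exponentially at its own
        rate: the rate function equals -k_i * phi_i exactly."""
        p = fig3.with_updates(mu_E=0.0, mu_L=0.0, mu_D=0.0, mu_N=0.0,
                              beta=0.0, sigma_N=0.0, basal_D=0.0, eta=0.0)
        f = CellFields(phi_E=2.0, phi_L=1.0, phi_D=0.5, phi_N=3.0, omega=0.0)
        dE, dL, dD, dN, _ = reaction_integrated(f, 0.0, p)
        assert float(dE) == pytest.approx(-p.k_E * 2.0)
        assert float(dL) == pytest.approx(-p.k_L * 1.0)
        assert float(dD) == pytest.approx(-p.k_D * 0.5)
        assert float(dN) == pytest.approx(-p.k_N * 3.0)


class TestModelParams:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(mu_E=-1.0)

    def test_integrated_requires_all_hills(self):
        with pytest.raises(ValueError):
            ModelParams(variant=Variant.INTEGRATED,
                        hill_specs={"E_auto": HillSpec()})

    def test_cellfields_validation(self):
        with pytest.raises(ValueError):
            CellFields(phi_E=-0.1).validate()
        with pytest.raises(ValueError):
            CellFields(omega=1.5).validate()
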