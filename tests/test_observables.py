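"""Wave metrics and pattern quantification on synthetic and simulated
tissues."""

import numpy as np
import pytest

from pnwave.fixtures import FixtureKind, make_fixture
from pnwave.lattice import build_chain, build_hex_disc, build_hex_rect
from pnwave.model_core import ModelParams, Variant
from pnwave.observables import (NO_FRONT, notch_prepeak, salt_and_pepper_index,
                                transition_zone_width, wave_speed,
                                wavefront_position, wave_metrics)
from pnwave.simulate import TissueState, Trajectory


def synthetic_trajectory(lattice, omega_per_time, params=None, times=None):
    T = len(omega_per_time)
    n = lattice.n_cells
    fields = {name: np.zeros((T, n)) for name in ("E", "L", "D", "N", "Omega")}
    fields["Omega"] = np.asarray(omega_per_time, dtype=float)
    p = params or ModelParams(variant=Variant.INTEGRATED)
    return Trajectory(times=np.asarray(times if times is not None else np.arange(T), dtype=float),
                      fields=fields, params=p, lattice=lattice)


class TestWavefrontPosition:
    def test_no_front_sentinel(self, chain40):
        st = TissueState(omega=np.zeros(40))
        assert wavefront_position(st, chain40) == NO_FRONT

    def test_step_interpolation(self):
        lat = build_hex_rect(20, 5)
        om = np.where(lat.column <= 9, 1.0, 0.0)
        st = TissueState(omega=om)
        assert wavefront_position(st, lat) == pytest.approx(9.5)

    def test_fixture_ground_truth(self, chain40):
        st, truth = make_fixture(FixtureKind.STEP_FRONT, chain40, column=12)
        assert wavefront_position(st, chain40) == pytest.approx(truth["front_position"])

    def test_simulated_front_non_decreasing(self, integrated_1d_run):
        tr = integrated_1d_run
        pos = [wavefront_position(tr.state(i), tr.lattice) for i in range(tr.n_times)]
        pos = [p for p in pos if np.isfinite(p)]
        assert all(b >= a - 1e-9 for a, b in zip(pos, pos[1:]))


class TestWaveSpeed:
    def test_unit_speed_constructed_front(self):
        lat = build_chain(60)
        om = np.array([[1.0 if c <= t else 0.0 for c in range(60)]
                       for t in range(0, 40)])
        traj = synthetic_trajectory(lat, om)
        speed, r2 = wave_speed(traj)
        assert speed == pytest.approx(1.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_stationary_profile_zero_speed(self):
        lat = build_chain(40)
        om = np.tile(np.where(np.arange(40) < 10, 1.0, 0.0), (20, 1))
        traj = synthetic_trajectory(lat, om)
        speed, _ = wave_speed(traj)
        assert speed == pytest.approx(0.0, abs=1e-12)

    def test_too_few_states_rejected(self):
        lat = build_chain(40)
        om = np.tile(np.where(np.arange(40) < 10, 1.0, 0.0), (2, 1))
        with pytest.raises(ValueError):
            wave_speed(synthetic_trajectory(lat, om))


class TestZoneWidth:
    def _traj_with_L(self, lattice, L_rows):
        T = len(L_rows)
        fields = {name: np.zeros((T, lattice.n_cells))
                  for name in ("E", "L", "D", "N", "Omega")}
        fields["L"] = np.asarray(L_rows, dtype=float)
        return Trajectory(times=np.arange(T, dtype=float), fields=fields,
                          params=ModelParams(variant=Variant.INTEGRATED),
                          lattice=lattice)

    def test_single_column_width_one(self):
        lat = build_chain(30)
        L = np.zeros((10, 30))
        L[:, 7] = 1.0
        assert transition_zone_width(self._traj_with_L(lat, L)) == pytest.approx(1.0)

    def test_gaussian_half_height_span(self, chain40):
        st, truth = make_fixture(FixtureKind.GAUSSIAN_PULSE, chain40,
                                 center=20, width=3.0)
        L = np.tile(st.phi_L, (10, 1))
        width = transition_zone_width(self._traj_with_L(chain40, L))
        assert width == pytest.approx(truth["half_height_span"], abs=1.0)

    def test_zero_L_gives_nan(self, chain40):
        L = np.zeros((10, 40))
        assert np.isnan(transition_zone_width(self._traj_with_L(chain40, L)))

    def test_e_only_variant_rejected(self, chain40, fig2a):
        fields = {name: np.zeros((5, 40)) for name in ("E", "L", "D", "N", "Omega")}
        traj = Trajectory(times=np.arange(5.0), fields=fields, params=fig2a,
                          lattice=chain40)
        with pytest.raises(ValueError):
            transition_zone_width(traj)

    def test_raising_lsc_production_tightens_zone(self, fig3):
        """Stronger L'sc expression terminates the transition faster and
        narrows the zone."""
        from pnwave.simulate import ICKind, InitialCondition, integrate
        lat = build_chain(50)
        ic = InitialCondition(kind=ICKind.LEFT_COLUMNS, n_columns=3)
        lo = integrate(fig3, lat, ic, t_end=40.0, dt=0.02, record_every=1.0)
        hi = integrate(fig3.with_updates(mu_L=2 * fig3.mu_L), lat, ic,
                       t_end=40.0, dt=0.02, record_every=1.0)
        assert transition_zone_width(hi) < transition_zone_width(lo)


class TestNotchPrepeak:
    def _traj_with_profiles(self, lattice, L, N):
        fields = {name: np.zeros((3, lattice.n_cells))
                  for name in ("E", "L", "D", "N", "Omega")}
        fields["L"][:] = L
        fields["N"][:] = N
        return Trajectory(times=np.arange(3, dtype=float), fields=fields,
                          params=ModelParams(variant=Variant.INTEGRATED),
                          lattice=lattice)

    def test_flat_notch_no_peak(self, chain40):
        L = np.zeros(40)
        L[10] = 1.0
        traj = self._traj_with_profiles(chain40, L, np.full(40, 5.0))
        found, _ = notch_prepeak(traj, 1.0)
        assert not found

    def test_constructed_plateau_bump_trough(self, chain40):
        N = np.full(40, 5.0)
        N[12] = 1.0      # trough at the zone
        N[14] = 7.0      # pre-peak two columns ahead
        L = np.zeros(40)
        L[12] = 1.0      # zone centre
        traj = self._traj_with_profiles(chain40, L, N)
        found, offset = notch_prepeak(traj, 0.0)
        assert found
        assert offset == pytest.approx(2.0)

    def test_integrated_run_shows_prepeak(self, integrated_1d_run):
        found, offset = notch_prepeak(integrated_1d_run, 40.0)
        assert found
        assert 0 < offset <= 5


class TestSaltAndPepperIndex:
    def test_constant_field_undefined(self, chain40):
        st = TissueState(phi_N=np.full(40, 2.0))
        assert np.isnan(salt_and_pepper_index(st, chain40))

    def test_chain_checkerboard_is_minus_one(self, chain40):
        st, truth = make_fixture(FixtureKind.CHECKERBOARD, chain40)
        idx = salt_and_pepper_index(st, chain40)
        assert idx == pytest.approx(truth["pattern_index"], abs=1e-12)

    def test_random_field_near_zero(self):
        """Permutation oracle: over 100 independently randomized fields the
        mean index is 0 within three standard errors."""
        lat = build_hex_disc(15)
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(100):
            st = TissueState(phi_N=rng.uniform(size=lat.n_cells))
            vals.append(salt_and_pepper_index(st, lat))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_affine_invariance(self, disc5, rng):
        f = rng.normal(size=disc5.n_cells)
        a = salt_and_pepper_index(TissueState(phi_N=f), disc5)
        b = salt_and_pepper_index(TissueState(phi_N=3.0 * f + 11.0), disc5)
        assert a == pytest.approx(b, abs=1e-12)

    def test_mask_restricts_pairs(self, chain40):
        f = (np.arange(40) % 2).astype(float)
        mask = np.zeros(40, dtype=bool)
        mask[:10] = True
        idx = salt_and_pepper_index(TissueState(phi_N=f), chain40, mask=mask)
        assert idx == pytest.approx(-1.0)


class TestWaveMetricsBundle:
    def test_fields_populated(self, integrated_1d_run):
        m = wave_metrics(integrated_1d_run)
        assert m.speed > 0
        assert 0 <= m.speed_r2 <= 1
        assert m.zone_width > 0
        assert m.front_positions.shape[1] == 2
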