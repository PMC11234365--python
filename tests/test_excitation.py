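import numpy as np
import pytest
from scipy import stats

from nmfit.density import cc_structure, simulate_map
from nmfit.excitation import (combine_modes, excite_velocities,
                              mode_probabilities, select_modes, trial_test)
from nmfit.model_io import kabsch_superpose
from nmfit.nma import ENMParams, full_modes
from nmfit.units import kinetic_energy


@pytest.fixture(scope="module")
def helix_modes(helix):
    return full_modes(helix, ENMParams(), 12)


class TestModeProbabilities:
    def test_equal_eigenvalues_uniform(self):
        p = mode_probabilities([2.0, 2.0, 2.0, 2.0])
        assert np.allclose(p, 0.25)

    def test_inverse_law_hand_computed(self):
        p = mode_probabilities([1.0, 2.0])
        assert p[0] == pytest.approx(2.0 / 3.0)
        assert p[1] == pytest.approx(1.0 / 3.0)

    def test_monotone_non_increasing(self, helix_modes):
        for law in ("inverse", "inverse_sqrt"):
            p = mode_probabilities(helix_modes.eigenvalues, law=law)
            assert (np.diff(p) <= 1e-15).all()
            assert p.sum() == pytest.approx(1.0)

    def test_nonpositive_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            mode_probabilities([0.0, 1.0])


class TestSelectModes:
    def test_pool_equal_k_returns_whole_pool(self, helix_modes, rng):
        idx = select_modes(helix_modes, k=3, pool_fraction=0.01, rng=rng)
        assert list(idx) == [0, 1, 2]

    def test_deterministic_given_seed(self, helix_modes):
        a = select_modes(helix_modes, 3, 0.5,
                         np.random.default_rng(42))
        b = select_modes(helix_modes, 3, 0.5,
                         np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_empirical_frequencies_match_inverse_law(self):
        """10^5 single-mode draws over a two-mode pool with eigenvalues
        (1, 2): mode 0 frequency ~ 2/3 within 3 sigma binomial error."""
        class TwoModes:
            eigenvalues = np.array([1.0, 2.0])
            n_modes = 2
        rng = np.random.default_rng(7)
        n = 100_000
        hits = sum(select_modes(TwoModes, 1, 1.0, rng)[0] == 0
                   for _ in range(n))
        p = 2.0 / 3.0
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(hits - n * p) < 3 * sigma

    def test_chi2_selection_distribution(self, helix_modes):
        """Single-mode selection over the 5 softest modes follows the
        inverse-eigenvalue law (chi-square not rejected at alpha=0.01)."""
        rng = np.random.default_rng(11)
        pool = 5
        pool_fraction = pool / helix_modes.n_modes
        n = 100_000
        counts = np.zeros(pool)
        for _ in range(n):
            counts[select_modes(helix_modes, 1, pool_fraction, rng)[0]] += 1
        expected = n * mode_probabilities(helix_modes.eigenvalues[:pool])
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        assert chi2 < stats.chi2.ppf(0.99, df=pool - 1)


class TestCombineModes:
    def test_single_mode_sign_preserved(self, helix_modes):
        c = combine_modes(helix_modes, [2], alphas=[0.3])
        w = helix_modes.masses[:, None]
        assert float(np.sum(w * c.Q * c.Q)) == pytest.approx(1.0, abs=1e-10)
        # normalisation erases magnitude but keeps the sign of alpha
        assert np.allclose(c.Q, helix_modes.modes[2], atol=1e-8)
        c2 = combine_modes(helix_modes, [2], alphas=[-0.3])
        assert np.allclose(c2.Q, -helix_modes.modes[2], atol=1e-8)

    def test_mass_normalisation_exact(self, helix_modes):
        c = combine_modes(helix_modes, [0, 1], alphas=[0.25, 0.25])
        w = helix_modes.masses[:, None]
        assert float(np.sum(w * c.Q * c.Q)) == pytest.approx(1.0, abs=1e-12)

    def test_no_component_along_unselected_modes(self, helix_modes, rng):
        c = combine_modes(helix_modes, [1, 3, 5], rng=rng)
        w = np.repeat(helix_modes.masses, 3)
        for j in (0, 2, 4, 6):
            proj = helix_modes.modes[j].ravel() @ (w * c.Q.ravel())
            assert abs(proj) < 1e-10

    def test_out_of_range_alpha_rejected(self, helix_modes):
        with pytest.raises(ValueError):
            combine_modes(helix_modes, [0], alphas=[0.7])

    def test_all_zero_alphas_rejected(self, helix_modes):
        with pytest.raises(ValueError):
            combine_modes(helix_modes, [0, 1], alphas=[0.0, 0.0])


class TestTrialTest:
    def test_zero_amplitude_rejected_by_strict_gate(self, toy_pair):
        s_open, s_closed, _ = toy_pair
        tm = simulate_map(s_closed, 5.0)
        cc_ref = cc_structure(s_open, tm, 5.0)
        ms = full_modes(s_open, ENMParams(), 5)
        accept, dcc, trial, _ = trial_test(s_open, ms.modes[0], 0.0, tm,
                                           5.0, cc_ref)
        assert not accept
        assert dcc == 0.0
        assert np.array_equal(trial.coords, s_open.coords)

    def test_hinge_mode_toward_target_accepted(self, toy_pair):
        """Displacing the open form along its internal open->closed
        difference direction (mass-normalised) must raise the correlation
        with the closed-form map."""
        s_open, s_closed, _ = toy_pair
        tm = simulate_map(s_closed, 5.0)
        cc_ref = cc_structure(s_open, tm, 5.0)
        # open and closed share the map frame, so the raw difference is
        # the direction that closes the hinge in the map
        Q = s_closed.coords - s_open.coords
        Q = Q / np.sqrt(np.sum(s_open.masses[:, None] * Q * Q))
        accept, dcc, trial, q_signed = trial_test(s_open, Q, 0.5, tm, 5.0,
                                                  cc_ref)
        assert accept
        assert dcc > 0
        assert cc_structure(trial, tm, 5.0) == pytest.approx(cc_ref + dcc,
                                                             abs=1e-12)

    def test_sign_reversal_recovers_productive_direction(self, toy_pair):
        s_open, s_closed, _ = toy_pair
        tm = simulate_map(s_closed, 5.0)
        cc_ref = cc_structure(s_open, tm, 5.0)
        Q = s_closed.coords - s_open.coords
        Q = Q / np.sqrt(np.sum(s_open.masses[:, None] * Q * Q))
        a_pos = trial_test(s_open, Q, 0.5, tm, 5.0, cc_ref)
        a_neg = trial_test(s_open, -Q, 0.5, tm, 5.0, cc_ref)
        assert a_pos[0] and a_neg[0]
        assert a_pos[1] == pytest.approx(a_neg[1], abs=1e-12)
        # both calls return the same productive signed direction
        assert np.allclose(a_pos[3], a_neg[3])

    def test_dcc_matches_independent_cc_recomputation(self, toy_pair, rng):
        s_open, s_closed, _ = toy_pair
        tm = simulate_map(s_closed, 5.0)
        cc_ref = cc_structure(s_open, tm, 5.0)
        ms = full_modes(s_open, ENMParams(), 5)
        c = combine_modes(ms, [0, 1, 2], rng=rng)
        accept, dcc, trial, q_signed = trial_test(s_open, c.Q, 0.5, tm, 5.0,
                                                  cc_ref)
        if accept:
            assert cc_structure(trial, tm, 5.0) - cc_ref == pytest.approx(
                dcc, abs=1e-10)
        # mass-weighted RMS displacement equals the requested amplitude
        scale = 0.5 * np.sqrt(s_open.masses.sum())
        for sign in (1, -1):
            disp = s_open.coords + sign * scale * c.Q
            mwrms = np.sqrt(np.sum(s_open.masses[:, None]
                                   * (disp - s_open.coords) ** 2)
                            / s_open.masses.sum())
            assert mwrms == pytest.approx(0.5, rel=1e-10)


class TestExciteVelocities:
    def test_injected_energy_equals_ek(self, helix_modes, helix):
        Q = helix_modes.modes[0]
        lam, q_exct, v_tot = excite_velocities(Q, helix.masses, 50.0,
                                               np.zeros_like(Q))
        assert kinetic_energy(helix.masses, q_exct) == pytest.approx(
            50.0, rel=1e-8)
        assert kinetic_energy(helix.masses, v_tot) == pytest.approx(
            50.0, rel=1e-8)

    def test_doubling_ek_scales_by_sqrt2(self, helix_modes, helix):
        Q = helix_modes.modes[1]
        lam1, q1, _ = excite_velocities(Q, helix.masses, 10.0, np.zeros_like(Q))
        lam2, q2, _ = excite_velocities(Q, helix.masses, 20.0, np.zeros_like(Q))
        assert lam2 / lam1 == pytest.approx(np.sqrt(2.0), rel=1e-12)
        assert np.linalg.norm(q2) / np.linalg.norm(q1) == pytest.approx(
            np.sqrt(2.0), rel=1e-12)

    def test_unit_round_trip_50_kcal(self, helix_modes, helix):
        """Independent unit-conversion oracle: recompute 1/2 sum m v^2 in
        kcal/mol from raw SI conversions and recover Ek = 50."""
        Q = helix_modes.modes[2]
        _, q_exct, _ = excite_velocities(Q, helix.masses, 50.0,
                                         np.zeros_like(Q))
        # v in Å/fs -> m/s; m in amu -> kg; E in J -> kcal/mol
        v_si = q_exct * 1e-10 / 1e-15
        m_kg = helix.masses * 1.66053906660e-27
        e_joule = 0.5 * float(np.sum(m_kg[:, None] * v_si ** 2))
        e_kcal_mol = e_joule * 6.02214076e23 / 4184.0
        assert e_kcal_mol == pytest.approx(50.0, rel=1e-4)

    def test_energy_balance_identity(self, helix_modes, helix, rng):
        """KE(v_tot) - KE(v_curr) = Ek + v_curr^T M Q_exct (in kcal/mol)."""
        from nmfit.units import KCAL_PER_AMU_A2_FS2

        Q = helix_modes.modes[0]
        v_curr = rng.normal(0, 0.002, Q.shape)
        _, q_exct, v_tot = excite_velocities(Q, helix.masses, 5.0, v_curr)
        lhs = (kinetic_energy(helix.masses, v_tot)
               - kinetic_energy(helix.masses, v_curr))
        cross = float(np.sum(helix.masses[:, None] * v_curr * q_exct)) \
            * KCAL_PER_AMU_A2_FS2
        assert lhs == pytest.approx(5.0 + cross, rel=1e-10)

    def test_nonpositive_ek_rejected(self, helix_modes, helix):
        with pytest.raises(ValueError):
            excite_velocities(helix_modes.modes[0], helix.masses, 0.0,
                              np.zeros((helix.n_atoms, 3)))
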