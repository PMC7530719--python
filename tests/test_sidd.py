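"""Superhelical melting model: energies, ensembles, profiles, peaks."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from mycsetpoint import sidd
from mycsetpoint.sidd import (
    EnsembleTooLargeError,
    InvalidAlphabetError,
    MeltState,
    SIDDParams,
    brute_force_profile,
    enumerate_states,
    find_melt_peaks,
    make_domain,
    melt_profile,
    residual_energy,
    state_energy,
)

THETA_INF = 1e9


def random_domain(n, seed, sigma=-0.06):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), n))
    return make_domain(seq, sigma=sigma)


class TestDomain:
    def test_zero_stress_alpha(self):
        assert make_domain("ATAT", sigma=0.0).alpha == 0.0

    def test_alpha_formula(self):
        d = make_domain("A" * 1040, sigma=-0.06)
        assert d.alpha == pytest.approx(-6.0)

    def test_invalid_base_position_reported(self):
        with pytest.raises(InvalidAlphabetError) as exc:
            make_domain("ATGN", sigma=0.0)
        assert exc.value.position == 3

    def test_lowercase_accepted(self):
        assert make_domain("atgc", sigma=0.0).sequence == "ATGC"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            make_domain("", sigma=0.0)


class TestStateEnergy:
    def test_helical_relaxed_is_zero(self):
        d = make_domain("ACGT" * 4, sigma=0.0)
        assert state_energy(d, MeltState(runs=(), G=0.0), SIDDParams()) == 0.0

    def test_helical_stressed_hand_value(self):
        # (K/2) * alpha^2 with K = 1.3, alpha = -6  ->  23.4 kcal/mol
        assert residual_energy(0, -6.0, 1.3, 10.4, 2.5) == pytest.approx(23.4)

    @pytest.mark.parametrize("n", [1, 5, 20, 60])
    @pytest.mark.parametrize("sigma", [0.0, -0.06, -0.12])
    def test_closed_form_matches_numeric_tau_minimization(self, n, sigma):
        """G_res must equal the minimum over interstrand twist tau of the
        explicit torsional + supercoiling energy."""
        p = SIDDParams()
        N = 100
        alpha = sigma * N / p.h
        K = p.K(N)

        def g_of_tau(tau):
            return 0.5 * p.C * n * tau**2 + 0.5 * K * (
                alpha + n / p.h - n * tau / (2 * math.pi)
            ) ** 2

        numeric = minimize_scalar(g_of_tau, bounds=(-10, 10), method="bounded",
                                  options={"xatol": 1e-12}).fun
        closed = residual_energy(n, alpha, K, p.h, p.C)
        assert closed == pytest.approx(numeric, abs=1e-8)


class TestEnumerate:
    def test_zero_stress_small_theta_gives_helical_only(self):
        p = SIDDParams(theta=5.0)  # < a + b_AT: no melted state admitted
        d = make_domain("ACGT" * 5, sigma=0.0)
        ens = enumerate_states(d, p)
        assert len(ens) == 1
        assert ens.states[0].runs == ()

    def test_homopolymer_single_run_matches_double_loop(self):
        """Exhaustive (start, length) oracle for max_runs = 1."""
        p = SIDDParams(max_runs=1, theta=8.0)
        d = make_domain("A" * 12, sigma=-0.08)
        ens = enumerate_states(d, p)
        # oracle: direct double loop over all windows
        N, K = d.N, p.K(d.N)
        energies = [residual_energy(0, d.alpha, K, p.h, p.C)]
        for start in range(N):
            for length in range(1, N - start + 1):
                g = p.a + p.b_AT * length + residual_energy(
                    length, d.alpha, K, p.h, p.C
                )
                energies.append(g)
        energies = np.array(energies)
        expected = int((energies <= energies.min() + p.theta + 1e-12).sum())
        assert len(ens) == expected

    def test_unrestricted_enumeration_counts_all_subsets(self):
        # theta = inf, max_runs = N: every open/closed configuration is a state
        p = SIDDParams(theta=THETA_INF, max_runs=10)
        d = make_domain("ACGTACGTAC", sigma=-0.06)
        assert len(enumerate_states(d, p)) == 2**10

    def test_state_cap_raises(self):
        p = SIDDParams(theta=THETA_INF)
        d = random_domain(16, seed=0)
        with pytest.raises(EnsembleTooLargeError):
            enumerate_states(d, p, max_states=100)

    def test_energies_sorted_and_consistent_with_state_energy(self):
        p = SIDDParams(theta=THETA_INF)
        d = random_domain(10, seed=1)
        ens = enumerate_states(d, p)
        G = ens.G
        assert np.all(np.diff(G) >= -1e-12)
        for st_ in ens.states[:50]:
            assert state_energy(d, st_, p) == pytest.approx(st_.G, abs=1e-9)


class TestProfiles:
    def test_helical_only_profile_is_zero(self):
        p = SIDDParams(theta=5.0)
        d = make_domain("GCGCGCGC", sigma=0.0)
        prof = melt_profile(enumerate_states(d, p))
        assert np.all(prof.p == 0)

    def test_palindromic_symmetry(self):
        # AT/GC composition symmetric about the center -> symmetric profile
        p = SIDDParams(theta=THETA_INF)
        d = make_domain("AATTGCGCGCTTAA", sigma=-0.08)
        prof = melt_profile(enumerate_states(d, p))
        assert np.allclose(prof.p, prof.p[::-1], atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    @pytest.mark.parametrize("sigma", [0.0, -0.06, -0.12])
    def test_matches_brute_force_n16(self, seed, sigma):
        p = SIDDParams(theta=THETA_INF)
        d = random_domain(16, seed=seed, sigma=sigma)
        prof = melt_profile(enumerate_states(d, p))
        oracle = brute_force_profile(d, p)
        assert np.abs(prof.p - oracle.p).max() < 1e-9

    def test_brute_force_two_state_hand_calculation(self):
        p = SIDDParams(max_runs=1)
        d = make_domain("A", sigma=0.0)
        prof = brute_force_profile(d, p)
        K = p.K(1)
        g_open = p.a + p.b_AT + residual_energy(1, 0.0, K, p.h, p.C)
        w = math.exp(-g_open / p.RT)
        assert prof.p[0] == pytest.approx(w / (1.0 + w), rel=1e-12)

    def test_at_melts_more_than_gc(self):
        p = SIDDParams(theta=THETA_INF)
        at = brute_force_profile(make_domain("A" * 8, sigma=-0.1), p)
        gc = brute_force_profile(make_domain("G" * 8, sigma=-0.1), p)
        assert at.p.sum() > gc.p.sum()

    def test_brute_force_refuses_large_n(self):
        with pytest.raises(ValueError):
            brute_force_profile(random_domain(23, seed=0))

    def test_stress_monotonicity_60bp(self):
        """Total melting is non-decreasing in |sigma|."""
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=60))
        sums = []
        for sigma in [0.0, -0.03, -0.06, -0.09]:
            d = make_domain(seq, sigma=sigma)
            prof = melt_profile(enumerate_states(d, SIDDParams()))
            sums.append(prof.p.sum())
        assert np.all(np.diff(sums) >= -1e-12)

    def test_at_island_captures_maximum(self):
        """An A/T island in a G/C background concentrates the melting."""
        seq = "G" * 25 + "AT" * 5 + "G" * 25
        d = make_domain(seq, sigma=-0.09)
        prof = melt_profile(enumerate_states(d, SIDDParams()))
        assert 25 <= int(np.argmax(prof.p)) < 35

    @given(
        seq=st.text(alphabet="ACGT", min_size=2, max_size=10),
        sigma=st.floats(min_value=-0.12, max_value=0.0),
    )
    def test_probability_bounds(self, seq, sigma):
        d = make_domain(seq, sigma=sigma)
        prof = melt_profile(enumerate_states(d, SIDDParams(theta=THETA_INF)))
        assert np.all(prof.p >= 0) and np.all(prof.p <= 1)


class TestPeaks:
    def test_flat_profile_no_peaks(self):
        prof = sidd.TransitionProbabilityProfile(p=np.zeros(10))
        assert find_melt_peaks(prof, 0.5) == []

    def test_single_peak_summit_and_distance(self):
        prof = sidd.TransitionProbabilityProfile(p=np.array([0, 0, 0.8, 0.9, 0.8, 0]))
        peaks = find_melt_peaks(prof, 0.5, anchor=10)
        assert len(peaks) == 1
        pk = peaks[0]
        assert (pk.start, pk.end, pk.summit) == (2, 5, 3)
        assert pk.distance_to_anchor == -7

    def test_plateau_ties_take_leftmost_summit(self):
        prof = sidd.TransitionProbabilityProfile(
            p=np.array([0, 0.8, 0.8, 0, 0.8, 0.8, 0])
        )
        peaks = find_melt_peaks(prof, 0.5)
        assert [pk.summit for pk in peaks] == [1, 4]
        best = sidd.strongest_peak(peaks)
        assert best.summit == 1

    def test_origin_offsets_coordinates(self):
        prof = sidd.TransitionProbabilityProfile(p=np.array([0, 0.9, 0]), origin=100)
        (pk,) = find_melt_peaks(prof, 0.5, anchor=110)
        assert pk.summit == 101 and pk.distance_to_anchor == -9

    def test_threshold_validation(self):
        prof = sidd.TransitionProbabilityProfile(p=np.zeros(3))
        with pytest.raises(ValueError):
            find_melt_peaks(prof, 1.5)
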