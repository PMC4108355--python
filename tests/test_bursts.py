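import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from loopburst.bursts import (
    InconsistentStatisticsError,
    burst_statistics,
    cross_strain_relations,
    fano_noise,
    invert_raw_stats,
    rho_from_equilibrium_constant,
)
from loopburst.params import RateParameters


def random_params(rng) -> RateParameters:
    return RateParameters(
        k_a=rng.uniform(0.01, 1.0),
        k_d1=rng.uniform(1e-4, 0.05),
        k_d2=rng.uniform(0.005, 0.2),
        k_d3=rng.uniform(0.1, 1.0),
        kl_12=rng.uniform(1.0, 10.0),
        kl_13=rng.uniform(5.0, 40.0),
        nu=rng.uniform(0.01, 0.5),
        g_m=rng.uniform(0.005, 0.05),
        k_p=rng.uniform(0.005, 0.05),
        g_p=rng.uniform(1e-5, 1e-3),
    )


class TestClosedForms:
    def test_uninduced_table_of_burst_statistics(self, uninduced):
        """Model-based burst decomposition at the uninduced parameter set:
        n_p=6.9, l_p=0.03, f~0.1, l_c~0.55, rho~0.2 (looping) and f=8,
        l_c~1.65 (deletion strain)."""
        s = burst_statistics(uninduced, "looping")
        assert s.n_p == pytest.approx(6.9, abs=0.05)
        assert s.l_p == pytest.approx(0.03, abs=1e-12)
        assert s.f == pytest.approx(0.1, abs=0.005)
        assert s.l_c == pytest.approx(0.55, abs=0.01)
        assert s.rho == pytest.approx(0.2, abs=0.01)
        s0 = burst_statistics(uninduced, "noaux")
        assert s0.f == pytest.approx(8.0, abs=1e-12)
        assert s0.l_c == pytest.approx(1.65, abs=0.01)

    def test_rho_from_equilibrium_constant(self):
        assert rho_from_equilibrium_constant(0.25) == pytest.approx(0.2)
        assert rho_from_equilibrium_constant(0.0) == 0.0

    def test_rho_equals_equilibrium_constant_formula(self, uninduced):
        """rho is completely determined by K = k_d2/k_a, the dissociation
        equilibrium constant of the transcribing auxiliary operator."""
        s = burst_statistics(uninduced, "looping")
        K = uninduced.k_d2 / uninduced.k_a
        assert s.rho == pytest.approx(rho_from_equilibrium_constant(K), rel=1e-12)

    def test_instant_relooping_kills_small_burst_size(self, uninduced):
        p = dataclasses.replace(uninduced, kl_12=1e9, kl_13=1e9)
        s = burst_statistics(p, "looping")
        assert s.l_p < 1e-9

    def test_looping_requires_aux_operators(self, uninduced_noaux):
        with pytest.raises(ValueError, match="auxiliary"):
            burst_statistics(uninduced_noaux, "looping")

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(seed=st.integers(0, 10**6))
    def test_decomposition_identity(self, seed):
        """Mean regulated transcription = n_p l_p + f l_c, exactly."""
        import warnings

        from loopburst.reduction import effective_rates

        rng = np.random.default_rng(seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = random_params(rng)
            s = burst_statistics(p, "looping")
            red = effective_rates(p)
        mean_tx = (red.nu_bound + red.kappa_f * p.nu / (3 * p.k_a)) / p.g_p
        assert s.mean_transcription == pytest.approx(mean_tx, rel=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10**6), scale=st.floats(0.01, 100.0))
    def test_rho_invariant_under_equilibrium_preserving_rescaling(
        self, seed, scale
    ):
        """rho depends only on k_d2/k_a: scaling both together leaves it
        unchanged."""
        import warnings

        rng = np.random.default_rng(seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = random_params(rng)
            q = dataclasses.replace(
                p, k_a=p.k_a * scale, k_d2=p.k_d2 * scale
            )
            r1 = burst_statistics(p, "looping").rho
            r2 = burst_statistics(q, "looping").rho
        assert r1 == pytest.approx(r2, rel=1e-9)


class TestFanoNoise:
    def test_no_large_bursts_leaves_translational_burstiness(self, uninduced):
        s = burst_statistics(uninduced, "looping")
        s0 = dataclasses.replace(s, rho=0.0)
        b = uninduced.k_p / uninduced.g_m
        fano, inv_noise = fano_noise(s0, b)
        assert fano == pytest.approx(1 + b)  # translational bursts only
        assert inv_noise == pytest.approx(
            b * s0.mean_transcription / (1 + b)
        )

    def test_matches_exact_moments_in_weak_induction(self, uninduced):
        from loopburst.analytic import moments_looping
        from loopburst.reduction import nondimensionalize

        s = burst_statistics(uninduced, "looping")
        b = uninduced.k_p / uninduced.g_m
        fano, inv_noise = fano_noise(s, b)
        m = moments_looping(nondimensionalize(uninduced))
        assert fano == pytest.approx(m.fano, rel=0.05)
        assert inv_noise == pytest.approx(m.inv_noise, rel=0.05)

    def test_zero_large_burst_size_single_term(self, uninduced):
        s = burst_statistics(uninduced, "looping")
        s0 = dataclasses.replace(s, l_c=0.0)
        b = 4.0
        fano, inv_noise = fano_noise(s0, b)
        assert fano == pytest.approx(1 + b)
        assert inv_noise == pytest.approx(b * s0.n_p * s0.l_p / (1 + b))


class TestInversion:
    def test_round_trip_recovers_lc_and_rho(self, uninduced):
        s = burst_statistics(uninduced, "looping")
        b = uninduced.k_p / uninduced.g_m
        fano, inv_noise = fano_noise(s, b)
        l_c, rho = invert_raw_stats(fano, inv_noise, b, s.f)
        assert l_c == pytest.approx(s.l_c, rel=1e-10)
        assert rho == pytest.approx(s.rho, rel=1e-10)

    def test_round_trip_over_titration_series(self, uninduced):
        """Point-wise inversion across decreasing association rates, the raw
        Fano/noise trajectory of an inducer titration."""
        b = uninduced.k_p / uninduced.g_m
        fanos, noises, truth = [], [], []
        f_ref = burst_statistics(uninduced, "looping").f
        for div in (1, 2, 5, 10, 20):
            p = dataclasses.replace(uninduced, k_a=uninduced.k_a / div)
            s = burst_statistics(p, "looping")
            fa, no = fano_noise(s, b)
            fanos.append(fa)
            noises.append(no)
            truth.append((s.l_c, s.rho))
        l_c, rho = invert_raw_stats(np.array(fanos), np.array(noises), b, f_ref)
        for (lc_t, rho_t), lc_e, rho_e in zip(truth, l_c, rho):
            assert lc_e == pytest.approx(lc_t, rel=1e-8)
            assert rho_e == pytest.approx(rho_t, rel=1e-8)
        # rho grows toward 1 with induction
        assert np.all(np.diff(rho) > 0)

    def test_fano_at_translational_floor_gives_zero_rho(self):
        l_c, rho = invert_raw_stats(5.0, 1.0, b=4.0, f=0.1)
        assert rho == 0.0

    def test_large_fano_drives_rho_toward_one(self):
        b, f = 4.0, 8.0
        # deletion-strain statistics: rho = 1 exactly
        l_c_true = 30.0
        fano = 1 + b * (1 + 1.0 * l_c_true)
        inv_noise = b * f * l_c_true / fano
        l_c, rho = invert_raw_stats(fano, inv_noise, b, f)
        assert rho == pytest.approx(1.0, rel=1e-9)
        assert l_c == pytest.approx(l_c_true, rel=1e-9)

    def test_inconsistent_inputs_flagged(self):
        with pytest.raises(InconsistentStatisticsError):
            invert_raw_stats(3.0, 1.0, b=4.0, f=0.1)  # fano < 1 + b
        with pytest.raises(InconsistentStatisticsError):
            # rho would exceed 1: excess larger than l_c can explain
            invert_raw_stats(50.0, 1e-4, b=4.0, f=1000.0)


class TestCrossStrain:
    def test_large_burst_size_ratio_is_exactly_one_third(self, uninduced):
        lc_ratio, _ = cross_strain_relations(uninduced)
        assert lc_ratio == pytest.approx(1.0 / 3.0, rel=1e-14)

    def test_frequency_ratio_about_one_eightieth(self, uninduced):
        _, f_ratio = cross_strain_relations(uninduced)
        assert 1 / f_ratio == pytest.approx(80.0, rel=0.05)

    def test_model_ratio_same_order_as_data_based_ratio(self, uninduced):
        # data-based frequencies from the titration plateaus: ~0.2 (looping)
        # and ~3 (deletion strain), i.e. ~1/15
        _, f_ratio = cross_strain_relations(uninduced)
        data_ratio = 0.2 / 3.0
        assert 0.1 < (f_ratio / data_ratio) < 10.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(ka=st.floats(1e-3, 1e3))
    def test_size_ratio_invariant_in_association_rate(self, uninduced, ka):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = dataclasses.replace(uninduced, k_a=ka)
            lc_ratio, _ = cross_strain_relations(p)
        assert lc_ratio == pytest.approx(1.0 / 3.0, rel=1e-12)
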