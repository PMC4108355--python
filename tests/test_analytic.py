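import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_dimensionless
from loopburst.analytic import (
    gf_ode_residual,
    gf_params_looping,
    gf_params_noaux,
    moments_from_gf,
    moments_looping,
    moments_noaux,
    negative_binomial_limit,
    pmf_from_gf,
    pmf_looping,
    pmf_noaux,
    total_variation,
)
from loopburst.fsp import fsp_reduced_steady_state
from loopburst.reduction import (
    DimensionlessParameters,
    dimensionless_noaux,
    nondimensionalize,
)


class TestGFParams:
    def test_vanishing_bound_transcription_reduces_to_noaux_family(self):
        d = DimensionlessParameters(a=30, b=2, gamma=500, kf=1.0, kb=1.0,
                                    phi_bound=0.0)
        assert gf_params_looping(d) == gf_params_noaux(d)

    def test_never_rebinding_gives_constitutive_negative_binomial(self):
        from scipy import stats

        d = DimensionlessParameters(a=20, b=2, gamma=500, kf=1.0, kb=0.0,
                                    phi_bound=0.0)
        dist = pmf_noaux(d)
        nb = stats.nbinom.pmf(np.arange(dist.pmf.size), d.a, 1 / (1 + d.b))
        assert total_variation(dist.pmf, nb) < 1e-10

    def test_non_finite_inputs_rejected(self):
        d = DimensionlessParameters(a=np.inf, b=2, gamma=500, kf=1, kb=1,
                                    phi_bound=0.0)
        with pytest.raises(ValueError):
            gf_params_looping(d)

    def test_ode_residual_small_on_unit_interval(self, uninduced):
        """The (A,B,C,c) mapping solves the generating-function ODE."""
        d = nondimensionalize(uninduced)
        assert gf_ode_residual(d) < 1e-8

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ode_residual_small_for_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        d = random_dimensionless(rng)
        assert gf_ode_residual(d) < 1e-8


class TestPmf:
    def test_no_transcription_gives_point_mass_at_zero(self):
        d = DimensionlessParameters(a=1e-12, b=2, gamma=500, kf=1.0, kb=5.0,
                                    phi_bound=0.0)
        dist = pmf_looping(d)
        assert dist.pmf[0] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reduced_model_fsp(self, seed):
        """Oracle equivalence: analytic pmf vs brute-force steady state of
        the reduced master equation, on random small parameter sets."""
        rng = np.random.default_rng(100 + seed)
        d = random_dimensionless(rng)
        ana = pmf_looping(d)
        fsp = fsp_reduced_steady_state(d, m_max=10, n_max=max(ana.n_max, 64))
        assert total_variation(ana.pmf, fsp.protein_marginal()) < 1e-3

    def test_uninduced_pmf_moments_match_closed_form(self, uninduced):
        d = nondimensionalize(uninduced)
        dist = pmf_looping(d)
        mom = moments_looping(d)
        assert dist.mean() == pytest.approx(mom.mean, rel=1e-6)
        assert dist.variance() == pytest.approx(mom.variance, rel=1e-6)

    def test_noaux_pmf_moments_match_closed_form(self, uninduced):
        d = dimensionless_noaux(uninduced)
        dist = pmf_noaux(d)
        mom = moments_noaux(d)
        assert dist.mean() == pytest.approx(mom.mean, rel=1e-6)
        assert dist.variance() == pytest.approx(mom.variance, rel=1e-6)

    def test_mixture_components_convolve_to_full_pmf(self, uninduced):
        """The small-burst (NB) and large-burst (NHG) sub-populations are
        independent and additive: their convolution is the full pmf."""
        d = nondimensionalize(uninduced)
        dist = pmf_looping(d)
        conv = np.convolve(dist.small_burst_pmf, dist.large_burst_pmf)
        assert total_variation(conv[: dist.pmf.size], dist.pmf) < 1e-12

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_normalization_and_positivity(self, seed):
        rng = np.random.default_rng(seed)
        d = random_dimensionless(rng)
        dist = pmf_looping(d)
        assert np.all(dist.pmf >= 0)
        assert 1 - 1e-9 <= dist.pmf.sum() <= 1 + 1e-12

    def test_explicit_small_nmax_warns_with_suggestion(self, uninduced):
        d = nondimensionalize(uninduced)
        with pytest.warns(UserWarning, match="tail mass"):
            pmf_looping(d, n_max=4)

    def test_pmf_against_independent_hypergeometric_series(self):
        """Cross-check the backward recurrence against direct arbitrary-
        precision differentiation of the generating function."""
        import mpmath as mp

        d = DimensionlessParameters(a=8.0, b=1.5, gamma=1000, kf=0.8, kb=6.0,
                                    phi_bound=0.0)
        gf = gf_params_noaux(d)
        dist = pmf_noaux(d)
        with mp.workdps(60):
            for n in (0, 1, 2, 5, 10, 25):
                mp_val = mp.diff(
                    lambda z: mp.hyp2f1(gf.A, gf.B, gf.C, gf.b * (z - 1)),
                    0,
                    n,
                ) / mp.factorial(n)
                assert dist.pmf[n] == pytest.approx(float(mp_val), rel=1e-9)


class TestMoments:
    def test_constitutive_mean_is_ab(self, uninduced):
        d = nondimensionalize(uninduced)
        kb0 = DimensionlessParameters(d.a, d.b, d.gamma, kf=1.0, kb=0.0,
                                      phi_bound=0.0)
        assert moments_noaux(kb0).mean == pytest.approx(2400.0, rel=1e-12)

    def test_no_translation_burst_limit_is_poissonian(self):
        d = DimensionlessParameters(a=20, b=1e-7, gamma=500, kf=1.0, kb=0.0,
                                    phi_bound=0.0)
        assert moments_noaux(d).fano == pytest.approx(1.0, abs=1e-5)

    def test_bursty_sets_are_super_poissonian(self, uninduced):
        assert moments_looping(nondimensionalize(uninduced)).fano > 1.0

    def test_weak_induction_flag_and_error(self, uninduced):
        m = moments_looping(nondimensionalize(uninduced))
        assert m.weak_induction_ok  # uninduced: ~0.04% of full induction
        assert m.weak_induction_rel_err < 0.05


class TestNegativeBinomialLimit:
    def test_convergence_is_monotone_in_association_rate(self, uninduced):
        """TV(exact, NB) decreases monotonically as k_a/nu sweeps up and
        drops below 1e-3 at the top of the sweep."""
        tvs = []
        for ratio in [0.1, 1.0, 10.0, 100.0, 1000.0]:
            p = dataclasses.replace(uninduced, k_a=ratio * uninduced.nu)
            d = nondimensionalize(p)
            exact = pmf_looping(d)
            nb, diag = negative_binomial_limit(d, "looping")
            tvs.append(total_variation(exact.pmf, nb.pmf))
            assert diag == pytest.approx(3 * ratio, rel=1e-9)
        assert all(a > b for a, b in zip(tvs, tvs[1:]))
        assert tvs[-1] < 1e-3
        assert tvs[0] > 0.05  # NB inadequate at slow association

    def test_nb_mean_equals_exact_mean(self, uninduced):
        p = dataclasses.replace(uninduced, k_a=100 * uninduced.nu)
        d = nondimensionalize(p)
        nb, _ = negative_binomial_limit(d, "looping")
        m = moments_looping(d)
        nb_mean = float(np.arange(nb.pmf.size) @ nb.pmf)
        assert nb_mean == pytest.approx(m.mean, rel=1e-6)

    def test_noaux_limit_also_converges(self, uninduced):
        p = dataclasses.replace(uninduced, k_a=200 * uninduced.nu)
        d = dimensionless_noaux(p)
        exact = pmf_noaux(d)
        nb, _ = negative_binomial_limit(d, "noaux")
        assert total_variation(exact.pmf, nb.pmf) < 1e-3
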