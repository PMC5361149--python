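"""FD, LF and EF estimators: exactness, invariances and orderings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octatten import (
    NormalizedSignal,
    ef_estimate,
    estimate,
    fd_estimate,
    harmonic_amplitudes,
    invert_harmonic_ratio,
    lf_estimate,
)
from octatten.estimators import (
    DispatchError,
    InsufficientDataError,
    LogDomainError,
    fd_estimate_batch,
    lf_estimate_batch,
)

from conftest import DZ, exponential_signal


def dft_modulus_oracle(values: np.ndarray, m: int) -> float:
    """Direct O(N^2)-style DFT sum, independent of the implementation."""
    N = len(values)
    total = 0.0 + 0.0j
    for n in range(N):
        total += values[n] * np.exp(-2j * np.pi * m * n / N)
    return abs(total)


class TestHarmonicAmplitudes:
    def test_constant_signal_has_no_first_harmonic(self):
        sig = NormalizedSignal(np.ones(64), 0.001, 0.064)
        assert harmonic_amplitudes(sig, 1) == pytest.approx(0.0, abs=1e-10)
        assert harmonic_amplitudes(sig, 0) == pytest.approx(64.0)

    @pytest.mark.parametrize("mu", [0.7, 3.0, 9.0])
    @pytest.mark.parametrize("m", [0, 1, 2, 5])
    def test_geometric_closed_form_and_direct_sum(self, mu, m):
        """|F(m)| of x^n matches both the geometric-series closed form
        and a brute-force DFT sum."""
        N = 128
        x = np.exp(-2 * mu * DZ)
        values = x ** np.arange(N)
        sig = NormalizedSignal(values, DZ, N * DZ)
        got = harmonic_amplitudes(sig, m)
        closed = abs(1 - x**N) / abs(1 - x * np.exp(-2j * np.pi * m / N))
        assert got == pytest.approx(closed, rel=1e-10)
        assert got == pytest.approx(dft_modulus_oracle(values, m), rel=1e-9)

    def test_too_few_samples_rejected(self):
        sig = NormalizedSignal(np.ones(3), 0.001, 0.003)
        with pytest.raises(InsufficientDataError):
            harmonic_amplitudes(sig, 0)


class TestFDEstimate:
    def test_constant_signal_gives_zero(self):
        sig = NormalizedSignal(np.ones(100), DZ, 100 * DZ)
        res = fd_estimate(sig)
        assert res.mu_rel == 0.0
        assert res.diagnostics["flat_signal"] is True

    def test_noiseless_exponential_exact(self):
        sig = exponential_signal(2.0, 400 * DZ)
        assert fd_estimate(sig).mu_rel == pytest.approx(2.0, rel=1e-6)

    def test_global_scale_cancels_exactly(self):
        a = exponential_signal(2.0, 0.35)
        b = exponential_signal(2.0, 0.35, amplitude=7.3)
        assert fd_estimate(b).mu_rel == fd_estimate(a).mu_rel

    def test_truncation_of_pure_exponential_is_invariant(self):
        """Dropping leading samples only rescales a pure exponential, so
        the FD estimate is unchanged — the mechanism behind its
        robustness to mis-detected surfaces."""
        n_full = 400
        z = np.arange(n_full + 25) * DZ
        full = np.exp(-2 * 2.0 * z)
        sig_a = NormalizedSignal(full[:n_full], DZ, n_full * DZ)
        sig_b = NormalizedSignal(full[25 : 25 + n_full], DZ, n_full * DZ)
        assert fd_estimate(sig_b).mu_rel == pytest.approx(
            fd_estimate(sig_a).mu_rel, rel=1e-9
        )

    def test_continuum_inversion_close_to_exact(self):
        sig = exponential_signal(3.0, 0.7)
        exact = fd_estimate(sig, inversion="exact").mu_rel
        cont = fd_estimate(sig, inversion="continuum").mu_rel
        # the two candidates differ by O(1/N)
        assert cont == pytest.approx(exact, rel=5.0 / sig.n_pixels)
        assert cont != exact

    def test_alternate_harmonic_pair(self):
        """Any pair m_lo < m_hi identifies the decay of an exponential."""
        sig = exponential_signal(4.0, 0.35)
        for pair in ((0, 2), (1, 2), (1, 3)):
            assert fd_estimate(sig, harmonics=pair).mu_rel == pytest.approx(
                4.0, rel=1e-6
            )

    def test_harmonic_ratio_monotone_in_mu(self):
        """r = |F0|/|F1| strictly increases with the decay rate."""
        ratios = []
        for mu in np.arange(0.5, 10.5, 0.5):
            sig = exponential_signal(mu, 0.35)
            res = fd_estimate(sig)
            ratios.append(res.diagnostics["harmonics"].ratio)
        # faster decay -> relatively larger first harmonic -> smaller r
        diffs = np.diff(ratios)
        assert np.all(diffs < 0) or np.all(diffs > 0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        mu=st.floats(0.2, 12.0),
        scale=st.floats(1e-3, 1e3),
        n=st.integers(50, 800),
    )
    def test_property_scale_invariance_and_exactness(self, mu, scale, n):
        z = np.arange(n) * DZ
        sig = NormalizedSignal(scale * np.exp(-2 * mu * z), DZ, n * DZ)
        assert fd_estimate(sig).mu_rel == pytest.approx(mu, rel=1e-6)


class TestLFEstimate:
    def test_constant_signal_gives_zero(self):
        sig = NormalizedSignal(np.ones(100), DZ, 100 * DZ)
        res = lf_estimate(sig)
        assert res.mu_rel == pytest.approx(0.0, abs=1e-12)
        assert res.diagnostics["slope"] == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_exponential_exact_with_unit_r2(self):
        sig = exponential_signal(2.0, 0.35)
        res = lf_estimate(sig)
        assert res.mu_rel == pytest.approx(2.0, rel=1e-12)
        assert res.diagnostics["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_polyfit_oracle_on_noisy_log_data(self):
        rng = np.random.default_rng(7)
        n = 200
        values = np.exp(-2 * 3.0 * np.arange(n) * DZ) * rng.lognormal(
            0, 0.2, size=n
        )
        sig = NormalizedSignal(values, DZ, n * DZ)
        slope_oracle = np.polyfit(np.arange(n) * DZ, np.log(values), 1)[0]
        assert lf_estimate(sig).mu_rel == pytest.approx(
            -slope_oracle / 2, rel=1e-9
        )

    def test_flat_tail_biases_slope_down(self):
        """An exponential that hits a flat floor fits a shallower line,
        underestimating the decay of the first segment."""
        n = 400
        z = np.arange(n) * DZ
        values = np.maximum(np.exp(-2 * 5.0 * z), 0.05)
        sig = NormalizedSignal(values, DZ, n * DZ)
        assert lf_estimate(sig).mu_rel < 5.0

    def test_nonpositive_value_names_pixel(self):
        # NormalizedSignal itself rejects zeros, so feed the raw vector
        values = np.ones(50)
        values[13] = 0.0
        with pytest.raises(LogDomainError, match="13"):
            lf_estimate(values)


class TestEFEstimate:
    def test_constant_signal_gives_zero(self):
        sig = NormalizedSignal(np.ones(100), DZ, 100 * DZ)
        res = ef_estimate(sig)
        assert res.mu_rel == pytest.approx(0.0, abs=1e-8)
        assert res.diagnostics["amplitude"] == pytest.approx(1.0, abs=1e-8)

    def test_noiseless_exponential_within_solver_tolerance(self):
        sig = exponential_signal(2.0, 0.35)
        res = ef_estimate(sig)
        assert res.mu_rel == pytest.approx(2.0, abs=1e-8)
        assert res.diagnostics["converged"]

    def test_flat_tail_bias_smaller_than_lf(self):
        """Linear-domain least squares weights the strong early samples,
        so EF underestimates less than LF on a floored exponential."""
        n = 400
        z = np.arange(n) * DZ
        values = np.maximum(np.exp(-2 * 5.0 * z), 0.05)
        sig = NormalizedSignal(values, DZ, n * DZ)
        bias_ef = abs(ef_estimate(sig).mu_rel - 5.0)
        bias_lf = abs(lf_estimate(sig).mu_rel - 5.0)
        assert bias_ef <= bias_lf

    def test_explicit_init_respected(self):
        sig = exponential_signal(1.0, 0.35)
        res = ef_estimate(sig, init=(1.0, 0.5))
        assert res.mu_rel == pytest.approx(1.0, abs=1e-8)


class TestDispatch:
    def test_reference_mu_is_additive(self):
        sig = exponential_signal(2.0, 0.35)
        res = estimate(sig, "FD", reference_mu=1.0)
        assert res.mu_sample == pytest.approx(res.mu_rel + 1.0, abs=1e-12)
        assert res.mu_sample == pytest.approx(3.0, rel=1e-6)

    def test_negative_relative_estimates_are_reported(self):
        """A growing ratio (sample less attenuating than the reference)
        must yield a negative mu_rel, not a clipped zero."""
        n = 400
        z = np.arange(n) * DZ
        sig = NormalizedSignal(np.exp(+2 * 0.5 * z), DZ, n * DZ)
        res = estimate(sig, "LF", reference_mu=0.3)
        assert res.mu_rel == pytest.approx(-0.5, rel=1e-9)
        assert res.mu_sample == pytest.approx(-0.2, rel=1e-6)

    def test_unknown_method_rejected(self):
        sig = exponential_signal(1.0, 0.35)
        with pytest.raises(DispatchError):
            estimate(sig, "XY")

    @pytest.mark.parametrize("mu", [0.5, 2.0, 5.0, 10.0])
    @pytest.mark.parametrize("window_mm", [0.35, 0.7, 1.05])
    def test_all_methods_agree_on_noiseless_input(self, mu, window_mm):
        sig = exponential_signal(mu, window_mm)
        results = [estimate(sig, m).mu_rel for m in ("FD", "LF", "EF")]
        for r in results:
            assert r == pytest.approx(mu, abs=1e-6)


class TestBatchPaths:
    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(3)
        n = 200
        z = np.arange(n) * DZ
        mus = rng.uniform(0.5, 8.0, size=10)
        values = np.exp(-2 * mus[:, None] * z[None, :]) * rng.uniform(
            0.9, 1.1, size=(10, n)
        )
        fd_b = fd_estimate_batch(values, DZ)
        lf_b = lf_estimate_batch(values, DZ)
        for i in range(10):
            sig = NormalizedSignal(values[i], DZ, n * DZ)
            assert fd_b[i] == pytest.approx(fd_estimate(sig).mu_rel, rel=1e-9)
            assert lf_b[i] == pytest.approx(lf_estimate(sig).mu_rel, rel=1e-9)
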