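"""Attenuation estimators: frequency-domain (FD), log-fit (LF), exponential fit (EF).

All three consume a :class:`~octatten.signal_model.NormalizedSignal`
``I(n*dz) = a * exp(-2 * mu_rel * n * dz)`` and return the relative
attenuation ``mu_rel`` in 1/mm.

FD — the fast, surface-robust method.  For a sampled exponential
``I(n) = a * x**n`` with per-pixel decay ``x = exp(-2 mu dz)``, the
modulus of the m-th DFT coefficient has the geometric-series closed
form ``|F(m)| = a * |1 - x**N| / |1 - x * exp(-i 2 pi m / N)|``.  The
ratio of any two harmonic moduli therefore depends only on ``x``; by
default the DC term and the first harmonic are used,

    r = |F(0)| / |F(1)|  =  |1 - x * exp(-i 2 pi / N)| / (1 - x),

which is inverted for ``x`` exactly (a quadratic; see
:func:`invert_harmonic_ratio`) and then ``mu_rel = -ln(x) / (2 dz)``.
The amplitude ``a`` cancels, so the estimate is invariant to global
scaling and to dropping leading samples of a pure exponential — the
mechanism behind FD's robustness to mis-detected surfaces.

LF — ordinary least squares of ``ln I`` on depth; ``mu_rel = -slope/2``.
Fast, but the logarithm weights the (noisy, multiply-scattered) tail
equally with the strong early signal.

EF — trust-region nonlinear least squares of ``a * exp(-2 mu z)`` in the
linear intensity domain; slowest, but the fit weight concentrates on
the large early samples, making it the most tail-robust.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .signal_model import ROUND_TRIP, EstimateResult, NormalizedSignal

#: |F(m_hi)| below this fraction of |F(m_lo)| is treated as a flat signal.
DEFAULT_F1_FLOOR = 1e-12

#: Tolerance on r >= 1 below which a signal is flagged non-decaying.
RATIO_TOL = 1e-9


class InsufficientDataError(ValueError):
    """Too few samples for the requested estimator."""


class LogDomainError(ValueError):
    """Non-positive value encountered where a logarithm is required."""


class DispatchError(ValueError):
    """Unknown estimator method tag."""


@dataclass(frozen=True)
class HarmonicPair:
    """DC / first-harmonic moduli and their ratio for one signal.

    ``nu0 = 1 / (N * dz)`` is the fundamental spatial frequency of the
    window; ``m_lo < m_hi`` are the harmonic orders compared.
    """

    F0: float
    F1: float
    ratio: float
    m_lo: int = 0
    m_hi: int = 1
    nu0: float = 0.0


def _as_values(signal) -> np.ndarray:
    if isinstance(signal, NormalizedSignal):
        return signal.values
    return np.asarray(signal, dtype=float)


def _dz_of(signal) -> float:
    """Pixel size of the signal; raw arrays default to 1 (per-pixel units)."""
    return signal.dz if isinstance(signal, NormalizedSignal) else 1.0


def harmonic_amplitudes(signal, m: int) -> float:
    """Modulus of the m-th DFT coefficient of the windowed signal.

    Computes ``|sum_n I(n dz) exp(-i 2 pi m n / N)|`` directly, with no
    spectral window or taper — the decay itself is the signal and
    tapering would bias the harmonic ratio.
    """
    values = _as_values(signal)
    N = values.size
    if N < 4:
        raise InsufficientDataError(f"need at least 4 samples, got {N}")
    if not (0 <= m <= N - 1):
        raise ValueError(f"harmonic order m={m} outside 0..{N - 1}")
    n = np.arange(N)
    return float(np.abs(np.sum(values * np.exp(-2j * np.pi * m * n / N))))


def invert_harmonic_ratio(
    r: float, N: int, m_lo: int = 0, m_hi: int = 1
) -> float:
    """Exact discrete inversion of the harmonic-modulus ratio.

    Solves ``r = |1 - x e^{-i th_hi}| / |1 - x e^{-i th_lo}|`` (with
    ``th_m = 2 pi m / N``) for the per-pixel decay ``x`` of a sampled
    exponential.  Squaring yields the quadratic

        (r^2 - 1) x^2 - 2 (r^2 cos th_lo - cos th_hi) x + (r^2 - 1) = 0

    whose two roots are reciprocal (``x`` and ``1/x``: the DFT moduli
    of a decay and of the reversed, growing signal coincide); the root
    in [0, 1) is returned.  ``r`` decreases toward 1 as the decay
    steepens; ``r <= 1`` (delta-like signal) maps to ``x = 0``.
    """
    th_lo = 2 * np.pi * m_lo / N
    th_hi = 2 * np.pi * m_hi / N
    a = r * r - 1.0
    if a <= 0:
        # For non-negative data |F(m_lo)| >= |F(m_hi)| (triangle
        # inequality), with equality only for a delta-like signal whose
        # decay is faster than one pixel: x -> 0.
        return 0.0
    b = r * r * np.cos(th_lo) - np.cos(th_hi)
    disc = b * b - a * a
    if disc < 0:
        raise ValueError(f"harmonic ratio r={r} not invertible for N={N}")
    x = (b - np.sqrt(disc)) / a
    return float(x)


def invert_harmonic_ratio_continuum(r: float, N: int, dz: float) -> float:
    """Continuum-limit inversion ``mu = (pi / L) / sqrt(r^2 - 1)``.

    Valid for the (0, 1) harmonic pair in the limit of fine sampling
    and a window much longer than the decay length; differs from the
    exact discrete inversion by O(1/N).  Returns ``mu_rel`` directly.
    """
    if r <= 1.0:
        return 0.0
    L = N * dz
    return float((np.pi / L) / np.sqrt(r * r - 1.0))


def fd_estimate(
    signal: NormalizedSignal,
    harmonics: Tuple[int, int] = (0, 1),
    inversion: str = "exact",
    f1_floor: float = DEFAULT_F1_FLOOR,
) -> EstimateResult:
    """Frequency-domain attenuation estimate from two harmonic moduli.

    Parameters
    ----------
    harmonics : (int, int)
        Orders ``(m_lo, m_hi)`` with ``m_lo < m_hi``; default DC vs
        first harmonic.
    inversion : {"exact", "continuum"}
        ``"exact"`` solves the discrete closed form (unbiased on
        sampled exponentials); ``"continuum"`` uses the analytic
        continuous-spectrum formula (only for the (0, 1) pair).
    f1_floor : float
        ``|F(m_hi)| < f1_floor * |F(m_lo)|`` is treated as a constant
        signal and returns ``mu_rel = 0`` with a flat-signal flag.
    """
    values = _as_values(signal)
    N = values.size
    if N < 4:
        raise InsufficientDataError(f"need at least 4 samples, got {N}")
    m_lo, m_hi = harmonics
    if not (0 <= m_lo < m_hi <= N - 1):
        raise ValueError(f"need 0 <= m_lo < m_hi <= N-1, got {harmonics}")
    n = np.arange(N)
    F_lo = float(np.abs(np.sum(values * np.exp(-2j * np.pi * m_lo * n / N))))
    F_hi = float(np.abs(np.sum(values * np.exp(-2j * np.pi * m_hi * n / N))))
    dz = _dz_of(signal)
    nu0 = 1.0 / (N * dz)
    warning = None

    if F_hi < f1_floor * F_lo:
        pair = HarmonicPair(F_lo, F_hi, np.inf, m_lo, m_hi, nu0)
        return EstimateResult(
            mu_rel=0.0,
            method="FD",
            diagnostics={"harmonics": pair, "flat_signal": True},
            window=(0, N),
        )

    r = F_lo / F_hi
    if r < 1.0 - RATIO_TOL:
        warning = "ill-posed signal: harmonic ratio below one"
        r = 1.0
    if inversion == "exact":
        x = invert_harmonic_ratio(r, N, m_lo, m_hi)
        if x > 0:
            mu_rel = -np.log(x) / (ROUND_TRIP * dz)
        else:
            mu_rel = np.inf
            warning = warning or "delta-like signal: decay faster than one pixel"
    elif inversion == "continuum":
        if (m_lo, m_hi) != (0, 1):
            raise ValueError("continuum inversion defined for harmonics (0, 1)")
        mu_rel = invert_harmonic_ratio_continuum(r, N, dz)
    else:
        raise ValueError(f"unknown inversion mode {inversion!r}")

    pair = HarmonicPair(F_lo, F_hi, r, m_lo, m_hi, nu0)
    diags: dict = {"harmonics": pair, "flat_signal": False}
    if warning:
        diags["quality_warning"] = warning
    return EstimateResult(
        mu_rel=float(mu_rel), method="FD", diagnostics=diags, window=(0, N)
    )


def lf_estimate(signal: NormalizedSignal) -> EstimateResult:
    """Log-and-fit: OLS of ``ln I`` on depth, ``mu_rel = -slope / 2``.

    Implemented with the four running sums (sum z, sum y, sum z*y,
    sum z^2) of simple linear regression, mirroring the four-parameter
    accumulation the method needs on streaming hardware.
    """
    values = _as_values(signal)
    N = values.size
    if N < 3:
        raise InsufficientDataError(f"need at least 3 samples, got {N}")
    bad = np.flatnonzero(values <= 0)
    if bad.size:
        raise LogDomainError(
            f"non-positive value at sample {int(bad[0])}: log undefined"
        )
    z = np.arange(N) * _dz_of(signal)
    y = np.log(values)
    Sz = z.sum()
    Sy = y.sum()
    Szy = (z * y).sum()
    Szz = (z * z).sum()
    denom = N * Szz - Sz * Sz
    slope = (N * Szy - Sz * Sy) / denom
    intercept = (Sy - slope * Sz) / N
    resid = y - (intercept + slope * z)
    ss_tot = float(np.sum((y - Sy / N) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return EstimateResult(
        mu_rel=float(-slope / ROUND_TRIP),
        method="LF",
        diagnostics={"slope": float(slope), "intercept": float(intercept), "r2": r2},
        window=(0, N),
    )


def ef_estimate(
    signal: NormalizedSignal,
    init: Optional[Tuple[float, float]] = None,
    mu_max: float = 50.0,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> EstimateResult:
    """Exponential fit: trust-region nonlinear least squares of a*exp(-2 mu z).

    ``init`` is an optional ``(amplitude, mu)`` start; by default the
    LF solution seeds the iteration (fast and usually close), falling
    back to ``(values[0], 1.0)`` when LF is unusable.  ``mu`` is bounded
    in ``[-mu_max, mu_max]``.  Non-convergence is reported through the
    ``converged`` diagnostic, never as an exception.
    """
    values = _as_values(signal)
    N = values.size
    if N < 3:
        raise InsufficientDataError(f"need at least 3 samples, got {N}")
    z = np.arange(N) * _dz_of(signal)

    if init is None:
        try:
            lf = lf_estimate(signal)
            a0 = float(np.exp(lf.diagnostics["intercept"]))
            mu0 = float(np.clip(lf.mu_rel, -mu_max, mu_max))
        except (LogDomainError, InsufficientDataError):
            a0, mu0 = float(values[0]), 1.0
    else:
        a0, mu0 = init
        mu0 = float(np.clip(mu0, -mu_max, mu_max))

    def resid(p: np.ndarray) -> np.ndarray:
        return p[0] * np.exp(-ROUND_TRIP * p[1] * z) - values

    def jac(p: np.ndarray) -> np.ndarray:
        e = np.exp(-ROUND_TRIP * p[1] * z)
        return np.column_stack((e, -ROUND_TRIP * p[0] * z * e))

    sol = least_squares(
        resid,
        x0=[a0, mu0],
        jac=jac,
        method="trf",
        bounds=([-np.inf, -mu_max], [np.inf, mu_max]),
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iter,
    )
    return EstimateResult(
        mu_rel=float(sol.x[1]),
        method="EF",
        diagnostics={
            "amplitude": float(sol.x[0]),
            "residual_norm": float(np.linalg.norm(sol.fun)),
            "converged": bool(sol.success),
            "n_evaluations": int(sol.nfev),
        },
        window=(0, N),
    )


_METHODS = {
    "FD": fd_estimate,
    "LF": lf_estimate,
    "EF": ef_estimate,
}


def estimate(
    signal: NormalizedSignal,
    method: str,
    reference_mu: Optional[float] = None,
    **kwargs,
) -> EstimateResult:
    """Dispatch to an estimator and attach the reference attenuation.

    ``mu_sample = mu_rel + reference_mu``; negative sample estimates
    are reported verbatim so diagnostic maps can expose surface-
    detection failures.
    """
    key = method.upper()
    if key not in _METHODS:
        raise DispatchError(f"unknown method {method!r}; expected FD, LF or EF")
    result = _METHODS[key](signal, **kwargs)
    if reference_mu is not None:
        result = result.with_reference(reference_mu)
    return result


# ---------------------------------------------------------------------------
# Vectorized batch paths.  These share the per-signal formulas above and are
# used by the mapping pipeline and the benchmark command, where thousands of
# windows are processed per frame.

def fd_estimate_batch(values: np.ndarray, dz: float) -> np.ndarray:
    """FD estimates for a batch of signals, one per row, (0,1) harmonics."""
    values = np.asarray(values, dtype=float)
    N = values.shape[1]
    n = np.arange(N)
    phase = np.exp(-2j * np.pi * n / N)
    F0 = np.abs(values.sum(axis=1))
    F1 = np.abs(values @ phase)
    r = np.where(F1 > DEFAULT_F1_FLOOR * F0, F0 / np.maximum(F1, 1e-300), np.inf)
    th = 2 * np.pi / N
    a = r * r - 1.0
    b = r * r - np.cos(th)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = (b - np.sqrt(np.maximum(b * b - a * a, 0.0))) / a
        mu = -np.log(x) / (ROUND_TRIP * dz)
    mu[~np.isfinite(r)] = 0.0  # flat signals
    return mu


def lf_estimate_batch(values: np.ndarray, dz: float) -> np.ndarray:
    """LF estimates for a batch of strictly positive signals, one per row."""
    values = np.asarray(values, dtype=float)
    N = values.shape[1]
    z = np.arange(N) * dz
    y = np.log(values)
    Sz = z.sum()
    Szz = (z * z).sum()
    Sy = y.sum(axis=1)
    Szy = y @ z
    slope = (N * Szy - Sz * Sy) / (N * Szz - Sz * Sz)
    return -slope / ROUND_TRIP


def ef_estimate_batch(values: np.ndarray, dz: float, mu_max: float = 50.0) -> np.ndarray:
    """EF estimates for a batch of signals (iterative; one solve per row)."""
    values = np.asarray(values, dtype=float)
    out = np.empty(values.shape[0])
    win_mm = values.shape[1] * dz
    for i in range(values.shape[0]):
        sig = NormalizedSignal(values[i], dz, win_mm)
        out[i] = ef_estimate(sig, mu_max=mu_max).mu_rel
    return out
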