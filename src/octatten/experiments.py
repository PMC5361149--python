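"""Seeded robustness studies comparing the FD, LF and EF estimators.

Each function reproduces one of the classic failure modes of
attenuation fitting on simulator output — mis-detected surfaces,
few-scattering tail contamination, residual speckle after lateral
averaging, and raw throughput — and returns summary statistics.  All
randomness derives from one integer seed, so every study is exactly
repeatable.
"""

from __future__ import annotations

import time
from typing import Dict, Tuple

import numpy as np

from . import estimators
from .preprocessing import extract_window
from .signal_model import ALineProfile, normalize
from .simulator import SimulationConfig, TailSpec, make_reference, simulate_volume

METHODS = ("FD", "LF", "EF")


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def surface_offset_study(
    seed: int,
    n_runs: int = 100,
    mu: float = 3.0,
    offsets_px: Tuple[int, ...] = (-30, -60),
    window_mm: float = 0.35,
    n_avg: int = 300,
    surface_mm: float = 0.1,
) -> Dict[int, Dict[str, np.ndarray]]:
    """Estimates under deliberately early (pre-surface) window starts.

    For each run, ``n_avg`` speckled A-lines of a homogeneous sample of
    attenuation ``mu`` are averaged, the fitting window is started
    ``offset_px`` pixels before the true surface (so it opens on noise-
    floor pixels), and all three estimators run on the normalized
    signal.  Returns ``{offset: {method: per-run mu_sample array}}``.
    """
    base = SimulationConfig(
        n_depth=700, n_alines=n_avg, n_frames=1, mu_field=mu,
        surface_height=surface_mm, speckle=True, noise_floor=1e-3, seed=0,
    )
    ref = make_reference(base, np.random.default_rng(seed))
    true_idx = int(np.ceil(surface_mm / base.dz))
    seeds = _child_seeds(seed + 1, n_runs)
    out = {off: {m: np.empty(n_runs) for m in METHODS} for off in offsets_px}
    for i, s in enumerate(seeds):
        cfg = SimulationConfig(
            n_depth=700, n_alines=n_avg, n_frames=1, mu_field=mu,
            surface_height=surface_mm, speckle=True, noise_floor=1e-3,
            seed=int(s), reference_averages=0,
        )
        vol, _, _ = simulate_volume(cfg)
        profile = ALineProfile(vol.data[0].mean(axis=0), cfg.dz)
        for off in offsets_px:
            window = extract_window(profile, true_idx + off, window_mm)
            sig = normalize(window, ref, 0, window_mm)
            for m in METHODS:
                out[off][m][i] = estimators.estimate(
                    sig, m, reference_mu=base.mu_ref
                ).mu_sample
    return out


def tail_bias_study(
    seed: int,
    n_runs: int = 40,
    mu: float = 7.0,
    c: float = 0.15,
    alpha: float = 0.3,
    window_mm: float = 1.05,
    n_avg: int = 300,
) -> Dict[str, Dict[str, float]]:
    """Signed estimator bias under few-scattering tail contamination.

    Long windows in highly attenuating tissue pick up multiply-
    scattered light; each run averages ``n_avg`` speckled A-lines with
    the two-exponential tail enabled and records ``mu_hat - mu`` per
    method.  Returns per-method ``{"bias": mean, "se": standard
    error}`` plus the EF-FD and FD-LF gap statistics.
    """
    tail = TailSpec(enabled=True, c=c, alpha=alpha)
    base = SimulationConfig(
        n_depth=1400, mu_field=mu, surface_height=0.0, tail=tail,
        speckle=True, noise_floor=1e-3, seed=0,
    )
    ref = make_reference(base, np.random.default_rng(seed))
    seeds = _child_seeds(seed + 1, n_runs)
    bias = {m: np.empty(n_runs) for m in METHODS}
    for i, s in enumerate(seeds):
        cfg = SimulationConfig(
            n_depth=1400, n_alines=n_avg, n_frames=1, mu_field=mu,
            surface_height=0.0, tail=tail, speckle=True, noise_floor=1e-3,
            seed=int(s), reference_averages=0,
        )
        vol, _, _ = simulate_volume(cfg)
        profile = ALineProfile(vol.data[0].mean(axis=0), cfg.dz)
        sig = normalize(extract_window(profile, 0, window_mm), ref, 0, window_mm)
        for m in METHODS:
            bias[m][i] = (
                estimators.estimate(sig, m, reference_mu=base.mu_ref).mu_sample
                - mu
            )
    result: Dict[str, Dict[str, float]] = {}
    for m in METHODS:
        result[m] = {
            "bias": float(bias[m].mean()),
            "se": float(bias[m].std(ddof=1) / np.sqrt(n_runs)),
        }
    for name, (hi, lo) in (("EF-FD", ("EF", "FD")), ("FD-LF", ("FD", "LF"))):
        gap = bias[hi] - bias[lo]
        result[name] = {
            "bias": float(gap.mean()),
            "se": float(gap.std(ddof=1) / np.sqrt(n_runs)),
        }
    return result


def speckle_averaging_study(
    seed: int,
    n_replicates: int = 200,
    mu: float = 3.0,
    n_small: int = 50,
    n_large: int = 300,
    window_mm: float = 0.35,
    method: str = "FD",
) -> Dict[str, float]:
    """Estimator spread versus number of laterally averaged A-lines.

    Each replicate draws ``n_large`` independent speckled A-lines and
    estimates once from the first ``n_small`` and once from all of
    them.  Averaging M exponentially distributed intensities shrinks
    the relative intensity SD like 1/sqrt(M), so the estimate SD ratio
    should approach ``sqrt(n_large / n_small)``.
    """
    base = SimulationConfig(
        n_depth=700, mu_field=mu, surface_height=0.0,
        speckle=True, noise_floor=1e-3, seed=0,
    )
    ref = make_reference(base, np.random.default_rng(seed))
    seeds = _child_seeds(seed + 1, n_replicates)
    est = {n_small: np.empty(n_replicates), n_large: np.empty(n_replicates)}
    for i, s in enumerate(seeds):
        cfg = SimulationConfig(
            n_depth=700, n_alines=n_large, n_frames=1, mu_field=mu,
            surface_height=0.0, speckle=True, noise_floor=1e-3,
            seed=int(s), reference_averages=0,
        )
        vol, _, _ = simulate_volume(cfg)
        for M in (n_small, n_large):
            profile = ALineProfile(vol.data[0, :M].mean(axis=0), cfg.dz)
            sig = normalize(
                extract_window(profile, 0, window_mm), ref, 0, window_mm
            )
            est[M][i] = estimators.estimate(
                sig, method, reference_mu=base.mu_ref
            ).mu_sample
    sd_small = float(est[n_small].std(ddof=1))
    sd_large = float(est[n_large].std(ddof=1))
    return {
        "sd_small": sd_small,
        "sd_large": sd_large,
        "ratio": sd_small / sd_large,
        "expected_ratio": float(np.sqrt(n_large / n_small)),
    }


def speed_study(
    seed: int,
    n_signals: int = 10_000,
    n_pixels: int = 398,
    mu: float = 3.0,
) -> Dict[str, float]:
    """Wall-clock time per method on one batch of windowed signals.

    Only the ratios are meaningful; absolute milliseconds depend on the
    host.  Returns seconds per method plus the EF/FD and EF/LF ratios.
    """
    rng = np.random.default_rng(seed)
    dz = 1.8 / 2048
    z = np.arange(n_pixels) * dz
    values = np.exp(-2 * mu * z) * rng.uniform(0.9, 1.1, (n_signals, n_pixels))
    times: Dict[str, float] = {}
    for name, fn in (
        ("FD", estimators.fd_estimate_batch),
        ("LF", estimators.lf_estimate_batch),
        ("EF", estimators.ef_estimate_batch),
    ):
        t0 = time.perf_counter()
        fn(values, dz)
        times[name] = time.perf_counter() - t0
    times["EF_over_FD"] = times["EF"] / times["FD"]
    times["EF_over_LF"] = times["EF"] / times["LF"]
    return times
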