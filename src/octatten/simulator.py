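"""Synthetic OCT volume generator with programmable attenuation fields.

The simulator produces volumes that follow the single-scattering decay
model exactly in the noiseless limit, and adds the three corruptions
the estimators must survive in practice:

* **speckle** — fully developed speckle makes the linear intensity of
  each pixel exponentially distributed around its mean (SD equals the
  mean), the standard statistics of coherent imaging of diffuse
  scatterers;
* **a few-scattering tail** — photons scattered more than once still
  reach the detector at depth; they are modelled as a second, slower
  exponential carrying a fraction ``c`` of the backscattered power and
  decaying at ``alpha * mu`` (``0 < alpha < 1``), flattening the tail
  the way multiply-scattered light does in highly attenuating tissue;
* **surface errors** — :func:`misdetect_surfaces` corrupts a detected
  surface map so pre-surface noise pixels leak into the fitted window.

Mean A-line above the surface:

    s(z) = A * mu_bs * h(z) * [(1-c) e^{-2 mu (z-z0)} + c e^{-2 alpha mu (z-z0)}] + floor

Above the surface only the noise floor remains.  A fixed seed makes
every output bit-identical between runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Union

import numpy as np

from .preprocessing import SurfaceMap
from .signal_model import ALineProfile, OCTVolume, ReferenceProfile, ROUND_TRIP


class SimulationConfigError(ValueError):
    """Invalid simulation configuration."""


#: Hard cap on generated samples (memory guard).
MAX_SAMPLES = 2**31

FieldLike = Union[float, Callable[[float, float], float]]


@dataclass(frozen=True)
class TailSpec:
    """Few-scattering contamination: fraction ``c`` at decay ``alpha * mu``."""

    enabled: bool = False
    c: float = 0.15
    alpha: float = 0.3

    def __post_init__(self) -> None:
        if not (0 <= self.c < 1):
            raise SimulationConfigError(f"need 0 <= c < 1, got {self.c}")
        if not (0 < self.alpha < 1):
            raise SimulationConfigError(f"need 0 < alpha < 1, got {self.alpha}")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one synthetic acquisition.

    ``mu_field`` and ``surface_height`` may be constants or callables
    of the lateral coordinates (x, y) in mm, giving the local
    attenuation (1/mm) and surface depth (mm).  Geometry defaults
    mirror a swept-source brain-imaging acquisition: a 1.8 mm depth
    range sampled at 2048 px (dz ~ 0.88 um) over a 2 x 2 mm field,
    scaled down in n_alines/n_frames for desk-size runs.
    """

    n_depth: int = 1400
    n_alines: int = 512
    n_frames: int = 4
    dz: float = 1.8 / 2048
    dx: float = 2.0 / 2048
    dy: float = 2.0 / 256
    mu_field: FieldLike = 3.0
    mu_ref: float = 1.0
    surface_height: FieldLike = 0.05
    amplitude: float = 1.0
    mu_bs: float = 1.0
    psf: Optional[np.ndarray] = None
    speckle: bool = True
    tail: TailSpec = field(default_factory=TailSpec)
    noise_floor: float = 1e-3
    reference_averages: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_depth", "n_alines", "n_frames"):
            if getattr(self, name) < 1:
                raise SimulationConfigError(f"{name} must be >= 1")
        for name in ("dz", "dx", "dy", "amplitude", "mu_bs"):
            if not (getattr(self, name) > 0):
                raise SimulationConfigError(f"{name} must be positive")
        if self.noise_floor < 0:
            raise SimulationConfigError("noise_floor must be >= 0")
        if not (self.mu_ref > 0):
            raise SimulationConfigError("mu_ref must be positive")
        n_total = self.n_depth * self.n_alines * self.n_frames
        if n_total > MAX_SAMPLES:
            raise SimulationConfigError(
                f"volume of {n_total} samples exceeds the {MAX_SAMPLES} guard"
            )

    def mu_at(self, x: float, y: float) -> float:
        return self.mu_field(x, y) if callable(self.mu_field) else float(self.mu_field)

    def surface_at(self, x: float, y: float) -> float:
        sh = self.surface_height
        return sh(x, y) if callable(sh) else float(sh)


def _mean_aline(config: SimulationConfig, mu: float, z0: float) -> np.ndarray:
    """Noise-free mean intensity for one column (without the floor)."""
    z = np.arange(config.n_depth) * config.dz
    if config.psf is None:
        h = np.ones(config.n_depth)
    else:
        h = np.asarray(config.psf, dtype=float)
        if h.shape != (config.n_depth,):
            raise SimulationConfigError(
                f"psf must have length n_depth={config.n_depth}"
            )
        if np.any(h <= 0):
            raise SimulationConfigError("psf must be strictly positive")
    c = config.tail.c if config.tail.enabled else 0.0
    alpha = config.tail.alpha
    s = np.zeros(config.n_depth)
    below = z >= z0
    depth = z[below] - z0
    decay = (1 - c) * np.exp(-ROUND_TRIP * mu * depth)
    if c > 0:
        decay = decay + c * np.exp(-ROUND_TRIP * alpha * mu * depth)
    s[below] = config.amplitude * config.mu_bs * h[below] * decay
    return s


def simulate_aline(
    config: SimulationConfig,
    x: float = 0.0,
    y: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> ALineProfile:
    """Generate one A-line at lateral position (x, y) in mm."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mu = config.mu_at(x, y)
    z0 = config.surface_at(x, y)
    mean = _mean_aline(config, mu, z0) + config.noise_floor
    if config.speckle:
        # fully developed speckle: exponential intensity with the local mean
        intensity = rng.exponential(scale=mean)
    else:
        intensity = mean
    return ALineProfile(intensity, config.dz)


def make_reference(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> ReferenceProfile:
    """Reference-phantom profile: flat surface at z0 = 0, mu = mu_ref.

    Generated with the same psf as the sample so normalization cancels
    it.  With speckle enabled the profile is the average of
    ``reference_averages`` independent speckled draws (the reference is
    measured once and averaged heavily in practice).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ref_cfg = replace(config, tail=TailSpec(enabled=False))
    mean = _mean_aline(ref_cfg, config.mu_ref, 0.0) + config.noise_floor
    if config.speckle and config.reference_averages > 0:
        draws = rng.exponential(
            scale=mean, size=(config.reference_averages, config.n_depth)
        )
        profile = draws.mean(axis=0)
    else:
        profile = mean
    return ReferenceProfile(
        profile=ALineProfile(profile, config.dz),
        mu_ref=config.mu_ref,
        surface_index=0,
    )


def simulate_volume(config: SimulationConfig):
    """Generate a full volume, its reference profile and the ground truth.

    Returns ``(OCTVolume, ReferenceProfile, mu_truth)`` where
    ``mu_truth`` has shape (n_frames, n_alines): the programmed
    attenuation at every lateral position.
    """
    rng = np.random.default_rng(config.seed)
    data = np.empty((config.n_frames, config.n_alines, config.n_depth))
    mu_truth = np.empty((config.n_frames, config.n_alines))
    xs = np.arange(config.n_alines) * config.dx
    ys = np.arange(config.n_frames) * config.dy
    varying = callable(config.mu_field) or callable(config.surface_height)
    if not varying:
        mean = _mean_aline(config, float(config.mu_field), float(config.surface_height))
        mean = mean + config.noise_floor
        mu_truth[:] = float(config.mu_field)
        if config.speckle:
            data[:] = rng.exponential(scale=mean, size=data.shape)
        else:
            data[:] = mean
    else:
        for fi, yv in enumerate(ys):
            for ai, xv in enumerate(xs):
                mu = config.mu_at(xv, yv)
                z0 = config.surface_at(xv, yv)
                mu_truth[fi, ai] = mu
                mean = _mean_aline(config, mu, z0) + config.noise_floor
                if config.speckle:
                    data[fi, ai] = rng.exponential(scale=mean)
                else:
                    data[fi, ai] = mean
    volume = OCTVolume(data, dz=config.dz, dx=config.dx, dy=config.dy)
    reference = make_reference(config, rng)
    return volume, reference, mu_truth


def misdetect_surfaces(
    surfaces: SurfaceMap,
    offset_px: Union[int, tuple],
    seed: Optional[int] = None,
) -> SurfaceMap:
    """Corrupt a surface map by a systematic or random pixel offset.

    ``offset_px`` is either one integer added to every detected index
    (negative = pre-surface: the fitted window then starts in the noise
    region above the tissue) or a ``(low, high)`` range sampled per
    entry with ``seed``.  Entries at -1 (not found) stay untouched.
    Offsets that push any index below 0 raise.
    """
    idx = surfaces.indices.copy()
    found = idx >= 0
    if isinstance(offset_px, tuple):
        rng = np.random.default_rng(seed)
        offsets = rng.integers(offset_px[0], offset_px[1] + 1, size=idx.shape)
    else:
        offsets = np.full(idx.shape, int(offset_px))
    shifted = idx[found] + offsets[found]
    if np.any(shifted < 0):
        raise ValueError("offset pushes a surface index below 0")
    idx[found] = shifted
    return SurfaceMap(
        indices=idx, method=surfaces.method + "+offset", confidence=surfaces.confidence
    )
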