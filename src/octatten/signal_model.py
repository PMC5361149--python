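"""Core domain types and the single-scattering OCT signal model.

The depth-dependent OCT intensity of a homogeneous turbid sample under
the single-scattering approximation is

    I_oct(z) = A * mu_bs * h(z) * exp(-2 * mu_ext * (z - z0)),   z >= z0

where ``A`` is a system constant, ``mu_bs`` the back-scattering
coefficient, ``h(z)`` the beam point-spread (confocal) function,
``mu_ext`` the total attenuation (extinction) coefficient in 1/mm and
``z0`` the sample surface.  Light traverses each depth twice
(illumination and backscatter collection), hence the round-trip factor
``ROUND_TRIP = 2`` in the exponent; every estimator and the simulator
share this one constant.

Dividing a sample A-line by the A-line of a homogeneous reference
phantom of known attenuation ``mu_ref`` (both re-indexed to start at
their own surface) cancels ``h(z)`` and the system constant, leaving a
pure exponential in the *relative* attenuation ``mu_rel = mu_sample -
mu_ref``.  All math in this package is on LINEAR intensity; readers
must convert dB-domain data before constructing these types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

import numpy as np

#: Round-trip exponent factor: intensity decays as exp(-2 mu z).
ROUND_TRIP: float = 2.0


class GeometryError(ValueError):
    """Invalid acquisition geometry (non-positive spacing, bad shape)."""


class NormalizationError(ValueError):
    """Reference signal unusable (zero/negative pixel) inside the window."""


class WindowOverflowError(ValueError):
    """Requested depth window does not fit inside a profile."""


@dataclass(frozen=True)
class ALineProfile:
    """One depth-resolved linear-intensity vector with its axial pixel size.

    Parameters
    ----------
    intensity : ndarray, shape (N,)
        Non-negative linear OCT intensity, arbitrary units.
    dz : float
        Axial pixel size in mm/pixel.
    """

    intensity: np.ndarray
    dz: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "intensity", arr)
        if arr.ndim != 1:
            raise GeometryError("intensity must be a 1-D vector")
        if not (self.dz > 0):
            raise GeometryError(f"dz must be positive, got {self.dz}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensity contains non-finite values")
        if np.any(arr < 0):
            raise ValueError("intensity contains negative values")

    @property
    def n_pixels(self) -> int:
        return self.intensity.shape[0]

    @property
    def depth_mm(self) -> float:
        return self.n_pixels * self.dz


@dataclass(frozen=True)
class OCTVolume:
    """3-D linear-intensity array ordered (frame, a_line, depth).

    ``dz`` is the axial pixel size, ``dx`` the lateral A-line spacing
    within a frame and ``dy`` the frame spacing, all in mm.
    """

    data: np.ndarray
    dz: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", arr)
        if arr.ndim != 3:
            raise GeometryError("volume data must be 3-D (frame, a_line, depth)")
        for name, v in (("dz", self.dz), ("dx", self.dx), ("dy", self.dy)):
            if not (v > 0):
                raise GeometryError(f"{name} must be positive, got {v}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_alines(self) -> int:
        return self.data.shape[1]

    @property
    def n_depth(self) -> int:
        return self.data.shape[2]

    def aline(self, frame: int, a_line: int) -> ALineProfile:
        return ALineProfile(self.data[frame, a_line, :], self.dz)


@dataclass(frozen=True)
class ReferenceProfile:
    """Laterally averaged reference-phantom A-line with known attenuation.

    ``mu_ref`` is the phantom's attenuation coefficient in 1/mm;
    ``surface_index`` is the first pixel at or below the phantom surface.
    """

    profile: ALineProfile
    mu_ref: float
    surface_index: int = 0

    def __post_init__(self) -> None:
        if not (self.mu_ref > 0):
            raise ValueError(f"mu_ref must be positive, got {self.mu_ref}")
        if not (0 <= self.surface_index < self.profile.n_pixels):
            raise ValueError("surface_index outside profile")


@dataclass(frozen=True)
class NormalizedSignal:
    """Sample/reference intensity ratio, re-indexed to start at the surface.

    Estimates from this signal are *relative* attenuations
    ``mu_rel = mu_sample - mu_ref``.
    """

    values: np.ndarray
    dz: float
    window_length_mm: float
    mu_is_relative: bool = True

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if not (self.dz > 0):
            raise GeometryError(f"dz must be positive, got {self.dz}")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise NormalizationError("normalized values must be finite and positive")
        if abs(self.window_length_mm - arr.size * self.dz) > self.dz:
            raise ValueError("window_length_mm inconsistent with values/dz")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def depth_axis(self) -> np.ndarray:
        """Depth in mm from the aligned surface, one entry per sample."""
        return np.arange(self.n_pixels) * self.dz


@dataclass(frozen=True)
class EstimateResult:
    """One attenuation estimate with its method tag and diagnostics.

    ``mu_rel`` may be negative (mis-detected surfaces produce negative
    fits; they are reported verbatim, never clipped).  ``mu_sample`` is
    ``mu_rel + mu_ref`` when a reference attenuation was attached,
    otherwise ``None``.
    """

    mu_rel: float
    method: str
    diagnostics: Mapping[str, object] = field(default_factory=dict)
    window: Tuple[int, int] = (0, 0)
    mu_sample: Optional[float] = None

    def with_reference(self, mu_ref: float) -> "EstimateResult":
        return EstimateResult(
            mu_rel=self.mu_rel,
            method=self.method,
            diagnostics=self.diagnostics,
            window=self.window,
            mu_sample=self.mu_rel + mu_ref,
        )


def forward_model(
    z0: float,
    A: float,
    mu_bs: float,
    mu_ext: float,
    psf,
    dz: float,
    n: int,
) -> ALineProfile:
    """Evaluate the single-scattering forward model on a depth grid.

    Parameters
    ----------
    z0 : float
        Surface depth in mm; pixels strictly above it are zero.
    A, mu_bs : float
        System constant and back-scattering coefficient (their product
        sets the overall amplitude).
    mu_ext : float
        Attenuation coefficient in 1/mm, ``>= 0``.
    psf : None, array_like or callable
        Beam focus function h(z): ``None`` means unity, an array is a
        tabulated per-pixel profile of length ``n``, a callable is
        evaluated at each depth (mm).  Must be strictly positive.
    dz : float
        Axial pixel size (mm).
    n : int
        Number of depth pixels, ``>= 2``.
    """
    if not (dz > 0) or n < 2:
        raise GeometryError(f"need dz > 0 and n >= 2, got dz={dz}, n={n}")
    if mu_ext < 0:
        raise ValueError(f"mu_ext must be >= 0, got {mu_ext}")
    z = np.arange(n) * dz
    h = _eval_psf(psf, z, n)
    out = np.zeros(n)
    below = z >= z0
    out[below] = A * mu_bs * h[below] * np.exp(-ROUND_TRIP * mu_ext * (z[below] - z0))
    return ALineProfile(out, dz)


def _eval_psf(psf, z: np.ndarray, n: int) -> np.ndarray:
    if psf is None:
        return np.ones(n)
    if callable(psf):
        h = np.asarray([psf(zi) for zi in z], dtype=float)
    else:
        h = np.asarray(psf, dtype=float)
        if h.shape != (n,):
            raise ValueError(f"tabulated psf must have length {n}, got {h.shape}")
    if np.any(h <= 0):
        raise ValueError("psf must be strictly positive over the depth range")
    return h


def normalize(
    sample: ALineProfile,
    reference: ReferenceProfile,
    sample_surface: int,
    window_mm: float,
) -> NormalizedSignal:
    """Divide a sample A-line by the reference A-line, surfaces aligned.

    Both profiles are re-indexed so that depth 0 is their own surface
    pixel before the elementwise division; the result covers
    ``floor(window_mm / dz)`` pixels.  The beam focus function and the
    system constant cancel in the ratio, so the ratio decays as
    ``exp(-2 * mu_rel * z)`` with ``mu_rel = mu_sample - mu_ref``.
    """
    ref = reference.profile
    if abs(sample.dz - ref.dz) > 1e-12:
        raise GeometryError(
            f"sample dz {sample.dz} and reference dz {ref.dz} differ"
        )
    if sample_surface < 0:
        raise ValueError(f"sample_surface must be >= 0, got {sample_surface}")
    n_win = int(np.floor(window_mm / sample.dz))
    if n_win < 1:
        raise WindowOverflowError(f"window {window_mm} mm shorter than one pixel")
    if sample_surface + n_win > sample.n_pixels:
        raise WindowOverflowError(
            f"window of {n_win} px from sample surface {sample_surface} "
            f"exceeds sample depth {sample.n_pixels}"
        )
    if reference.surface_index + n_win > ref.n_pixels:
        raise WindowOverflowError(
            f"window of {n_win} px from reference surface "
            f"{reference.surface_index} exceeds reference depth {ref.n_pixels}"
        )
    s = sample.intensity[sample_surface : sample_surface + n_win]
    r = ref.intensity[reference.surface_index : reference.surface_index + n_win]
    bad = np.flatnonzero(r <= 0)
    if bad.size:
        raise NormalizationError(
            f"reference pixel {reference.surface_index + bad[0]} is "
            "non-positive inside the normalization window"
        )
    values = s / r
    if np.any(values <= 0):
        # zero sample intensity cannot be log-/ratio-processed downstream
        first = int(np.flatnonzero(values <= 0)[0])
        raise NormalizationError(
            f"sample pixel {sample_surface + first} is non-positive "
            "inside the normalization window"
        )
    return NormalizedSignal(
        values=values, dz=sample.dz, window_length_mm=n_win * sample.dz
    )
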