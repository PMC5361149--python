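"""En-face attenuation maps, diagnostic classification and rendering.

One attenuation value is estimated per (lateral window, frame) cell:
average -> detect surface -> cut data-length window -> normalize by the
reference -> estimate -> ``mu_sample = mu_rel + mu_ref``.  The
resulting 2-D grid is classified against a diagnostic threshold
(attenuation below the cutoff marks high cancer density; healthy white
matter attenuates strongly) and rendered as a red-to-green colour map.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import matplotlib
import numpy as np

from . import estimators
from .preprocessing import (
    AveragingSpec,
    SurfaceMap,
    SurfaceParams,
    detect_surfaces,
    extract_window,
    lateral_average,
)
from .signal_model import (
    ALineProfile,
    GeometryError,
    NormalizationError,
    OCTVolume,
    ReferenceProfile,
    WindowOverflowError,
    normalize,
)

LABEL_HIGH_CANCER = "high-cancer-density"
LABEL_LOW_CANCER = "low-cancer-density"
LABEL_UNKNOWN = "unknown"


@dataclass(frozen=True)
class MapConfig:
    """Pipeline settings for one en-face map."""

    method: str = "FD"
    data_length_mm: float = 0.35
    averaging: AveragingSpec = field(default_factory=AveragingSpec)
    surface: SurfaceParams = field(default_factory=SurfaceParams)
    harmonics: Tuple[int, int] = (0, 1)
    inversion: str = "exact"
    ef_mu_max: float = 50.0


@dataclass(frozen=True)
class ClassificationRule:
    """Attenuation cutoffs for tissue labelling.

    ``threshold_mm1`` (default 5.5 1/mm) separates high cancer density
    (below) from low cancer density / mostly white matter (at or
    above); ties go to "above" — conservative toward non-cancer.
    ``band_threshold_mm1`` is an optional secondary boundary (default
    3.75 1/mm) used for delineating high-attenuation bands in phantom
    maps.
    """

    threshold_mm1: float = 5.5
    band_threshold_mm1: Optional[float] = 3.75
    label_below: str = LABEL_HIGH_CANCER
    label_above: str = LABEL_LOW_CANCER

    def __post_init__(self) -> None:
        if not (self.threshold_mm1 > 0):
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class AttenuationMap:
    """2-D grid of sample attenuation coefficients (1/mm).

    ``mu`` is ordered (frame, lateral window); ``mask`` is True where
    the cell is valid (surface found, window fitted, estimator
    converged to a finite value).  ``x_mm``/``y_mm`` are the physical
    window-centre coordinates.
    """

    mu: np.ndarray
    mask: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    spec: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mu.shape != self.mask.shape:
            raise ValueError("mu and mask shapes differ")
        if np.any(~np.isfinite(self.mu[self.mask])):
            raise ValueError("non-finite mu inside the valid mask")

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


def build_map(
    volume: OCTVolume,
    reference: ReferenceProfile,
    config: MapConfig = MapConfig(),
    surfaces: Optional[SurfaceMap] = None,
) -> AttenuationMap:
    """Run the full per-cell pipeline over a volume.

    ``surfaces`` overrides automatic detection (used to study the
    effect of mis-detected surfaces); cells whose surface is missing,
    whose window overflows the depth range or whose estimate is
    non-finite are masked rather than raising.
    """
    if abs(volume.dz - reference.profile.dz) > 1e-12:
        raise GeometryError(
            f"volume dz {volume.dz} and reference dz {reference.profile.dz} differ"
        )
    profiles, x_mm = lateral_average(volume, config.averaging)
    if surfaces is None:
        surfaces = detect_surfaces(profiles, volume.dz, config.surface)
    n_frames, n_win, _ = profiles.shape
    if surfaces.indices.shape != (n_frames, n_win):
        raise ValueError(
            f"surface map shape {surfaces.indices.shape} does not match "
            f"grid {(n_frames, n_win)}"
        )
    mu = np.full((n_frames, n_win), np.nan)
    mask = np.zeros((n_frames, n_win), dtype=bool)
    for f in range(n_frames):
        for w in range(n_win):
            s_idx = int(surfaces.indices[f, w])
            if s_idx < 0:
                continue
            profile = ALineProfile(profiles[f, w], volume.dz)
            try:
                windowed = extract_window(profile, s_idx, config.data_length_mm)
                signal = normalize(windowed, reference, 0, config.data_length_mm)
                kwargs: Dict[str, object] = {}
                if config.method.upper() == "FD":
                    kwargs = {
                        "harmonics": config.harmonics,
                        "inversion": config.inversion,
                    }
                elif config.method.upper() == "EF":
                    kwargs = {"mu_max": config.ef_mu_max}
                result = estimators.estimate(
                    signal, config.method, reference_mu=reference.mu_ref, **kwargs
                )
            except (WindowOverflowError, NormalizationError,
                    estimators.LogDomainError, estimators.InsufficientDataError):
                continue
            if result.diagnostics.get("converged") is False:
                continue
            if np.isfinite(result.mu_sample):
                mu[f, w] = result.mu_sample
                mask[f, w] = True
    y_mm = np.arange(n_frames) * volume.dy
    return AttenuationMap(
        mu=mu,
        mask=mask,
        x_mm=np.asarray(x_mm),
        y_mm=y_mm,
        spec={
            "method": config.method.upper(),
            "data_length_mm": config.data_length_mm,
            "averaging_window": config.averaging.window_alines,
            "averaging_step": config.averaging.step_alines,
            "mu_ref": reference.mu_ref,
        },
    )


def classify(amap: AttenuationMap, rule: ClassificationRule) -> np.ndarray:
    """Label each cell by the diagnostic threshold.

    Attenuation strictly below ``threshold_mm1`` -> ``label_below``
    (high cancer density); at or above -> ``label_above``; masked
    cells -> ``unknown``.  Idempotent and total over valid cells.
    """
    labels = np.full(amap.mu.shape, LABEL_UNKNOWN, dtype=object)
    valid = amap.mask
    below = valid & (amap.mu < rule.threshold_mm1)
    labels[below] = rule.label_below
    labels[valid & ~below] = rule.label_above
    return labels


def compare_maps(a: AttenuationMap, b: AttenuationMap) -> Tuple[float, float]:
    """Mean and SD of the elementwise difference a - b over valid cells.

    Shapes must match; the comparison runs over the intersection of
    the two validity masks.
    """
    if a.mu.shape != b.mu.shape:
        raise ValueError(f"map shapes differ: {a.mu.shape} vs {b.mu.shape}")
    both = a.mask & b.mask
    if not both.any():
        raise ValueError("no jointly valid cells to compare")
    delta = a.mu[both] - b.mu[both]
    return float(delta.mean()), float(delta.std())


def _colormap_rgb(
    mu: np.ndarray, mask: np.ndarray, mu_range: Tuple[float, float]
) -> np.ndarray:
    """Map attenuation to red(low) -> yellow -> green(high); gray masked."""
    lo, hi = mu_range
    cmap = matplotlib.colormaps["RdYlGn"]
    t = np.clip((mu - lo) / (hi - lo), 0.0, 1.0)
    t = np.where(np.isfinite(t), t, 0.0)
    rgb = cmap(t)[..., :3]
    rgb[~mask] = 0.5  # gray, distinguishable from low-signal black
    return (rgb * 255 + 0.5).astype(np.uint8)


def render(
    amap: AttenuationMap,
    rule: ClassificationRule,
    out_prefix,
    mu_range: Tuple[float, float] = (0.0, 10.0),
) -> Dict[str, Path]:
    """Write the map as an RGB PNG and a CSV grid with coordinates.

    The CSV carries one row per cell: x_mm, y_mm, mu_mm1 (6 significant
    digits), label, mask.  Returns the paths written.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    png_path = out_prefix.with_suffix(".png")
    csv_path = out_prefix.with_suffix(".csv")

    rgb = _colormap_rgb(amap.mu, amap.mask, mu_range)
    from PIL import Image

    Image.fromarray(rgb, mode="RGB").save(png_path)

    labels = classify(amap, rule)
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_mm", "y_mm", "mu_mm1", "label", "mask"])
        n_frames, n_win = amap.mu.shape
        for f in range(n_frames):
            for w in range(n_win):
                mu_str = (
                    format(amap.mu[f, w], ".6g") if amap.mask[f, w] else "nan"
                )
                writer.writerow(
                    [
                        format(amap.x_mm[w], ".6g"),
                        format(amap.y_mm[f], ".6g"),
                        mu_str,
                        labels[f, w],
                        int(amap.mask[f, w]),
                    ]
                )
    return {"png": png_path, "csv": csv_path}


def read_map_csv(path) -> AttenuationMap:
    """Read a map CSV written by :func:`render` back into an AttenuationMap."""
    import pandas as pd

    df = pd.read_csv(path)
    xs = np.unique(df["x_mm"].to_numpy())
    ys = np.unique(df["y_mm"].to_numpy())
    n_win, n_frames = xs.size, ys.size
    mu = df["mu_mm1"].to_numpy(dtype=float).reshape(n_frames, n_win)
    mask = df["mask"].to_numpy(dtype=bool).reshape(n_frames, n_win)
    return AttenuationMap(mu=mu, mask=mask, x_mm=xs, y_mm=ys)
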