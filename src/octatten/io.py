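"""File formats, run configuration and the end-to-end pipeline.

Volumes travel as multi-frame TIFF (one frame per page) or raw binary,
either way accompanied by a small JSON sidecar declaring dtype, shape,
axis order, pixel spacings and the intensity domain (linear or dB).
Reference profiles are two-column CSV with hash-comment headers.  A
YAML run configuration, validated against a strict schema (unknown
keys rejected), drives the pipeline; every run emits a JSON manifest
embedding the configuration and its hash so any artifact can be traced
back to the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .mapping import (
    AttenuationMap,
    ClassificationRule,
    MapConfig,
    build_map,
    compare_maps,
    render,
)
from .preprocessing import AveragingSpec, SurfaceParams
from .signal_model import ALineProfile, OCTVolume, ReferenceProfile


class FormatError(ValueError):
    """File contents disagree with the declared format."""


_AXES = ("frame", "a_line", "depth")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: OCTVolume, path, intensity_domain: str = "linear") -> Path:
    """Write a volume as multi-frame TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.data.astype(np.float32))
    sidecar = {
        "dtype": "float32",
        "shape": list(volume.data.shape),
        "axes": list(_AXES),
        "dz": volume.dz,
        "dx": volume.dx,
        "dy": volume.dy,
        "intensity_domain": intensity_domain,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_volume(path, sidecar=None) -> OCTVolume:
    """Read a TIFF or raw-binary volume into linear intensity.

    The sidecar (default ``<path>.json``) must declare dtype, shape,
    axis order, spacings and intensity domain; dB-domain data
    (``stored = 10 log10 I``) is converted back to linear on read.
    Axis order is normalized to (frame, a_line, depth).
    """
    path = Path(path)
    sidecar_path = Path(sidecar) if sidecar else _sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("dtype", "shape", "axes", "dz", "dx", "dy", "intensity_domain"):
        if key not in meta:
            raise FormatError(f"sidecar missing key {key!r}")
    shape = tuple(meta["shape"])
    if path.suffix.lower() in (".tif", ".tiff"):
        data = np.asarray(tifffile.imread(path))
    else:
        data = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
        expected = int(np.prod(shape))
        if data.size != expected:
            raise FormatError(
                f"raw file holds {data.size} samples "
                f"({data.size * data.itemsize} bytes), sidecar declares "
                f"{expected} ({expected * data.itemsize} bytes)"
            )
        data = data.reshape(shape)
    if data.shape != shape:
        raise FormatError(f"file shape {data.shape} != sidecar shape {shape}")
    axes = list(meta["axes"])
    if sorted(axes) != sorted(_AXES):
        raise FormatError(f"sidecar axes must be a permutation of {_AXES}")
    data = np.transpose(data, [axes.index(a) for a in _AXES])
    domain = meta["intensity_domain"]
    if domain == "dB":
        data = np.power(10.0, data.astype(float) / 10.0)
    elif domain != "linear":
        raise FormatError(f"unknown intensity_domain {domain!r}")
    return OCTVolume(
        data.astype(float), dz=float(meta["dz"]), dx=float(meta["dx"]), dy=float(meta["dy"])
    )


def write_reference(reference: ReferenceProfile, path) -> Path:
    """Write a reference profile as headered CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        f"# mu_ref_mm-1={float(reference.mu_ref):.17g}",
        f"# dz_mm={float(reference.profile.dz):.17g}",
        f"# surface_index={reference.surface_index}",
        "pixel_index,intensity",
    ]
    for i, v in enumerate(reference.profile.intensity):
        lines.append(f"{i},{float(v):.17g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_reference(path) -> ReferenceProfile:
    """Read a reference-profile CSV written by :func:`write_reference`."""
    path = Path(path)
    header: Dict[str, str] = {}
    rows: List[Tuple[int, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                header[key.strip()] = value.strip()
            elif line[0].isdigit() or line[0] == "-":
                idx_s, _, val_s = line.partition(",")
                rows.append((int(idx_s), float(val_s)))
    if "mu_ref_mm-1" not in header:
        raise FormatError("reference CSV missing '# mu_ref_mm-1=' header")
    if "dz_mm" not in header:
        raise FormatError("reference CSV missing '# dz_mm=' header")
    rows.sort()
    intensity = np.array([v for _, v in rows])
    return ReferenceProfile(
        profile=ALineProfile(intensity, float(header["dz_mm"])),
        mu_ref=float(header["mu_ref_mm-1"]),
        surface_index=int(header.get("surface_index", 0)),
    )


# ---------------------------------------------------------------------------
# Run configuration (strict schema)

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AveragingBlock(_Strict):
    window: int = 330
    step: int = 13


class SurfaceBlock(_Strict):
    smooth_px: int = 5
    k_sd: float = 4.0
    noise_region_px: int = 50


class EstimatorBlock(_Strict):
    harmonics: List[int] = Field(default_factory=lambda: [0, 1])
    inversion: str = "exact"
    ef_mu_max: float = 50.0


class ClassificationBlock(_Strict):
    threshold_mm1: float = 5.5
    band_threshold_mm1: Optional[float] = 3.75


class RunConfig(_Strict):
    """Schema-validated settings for one mapping run."""

    volume: str
    reference: str
    sidecar: Optional[str] = None
    methods: List[str] = Field(default_factory=lambda: ["FD"])
    data_length_mm: float = 0.35
    averaging: AveragingBlock = Field(default_factory=AveragingBlock)
    surface: SurfaceBlock = Field(default_factory=SurfaceBlock)
    estimator: EstimatorBlock = Field(default_factory=EstimatorBlock)
    classification: ClassificationBlock = Field(default_factory=ClassificationBlock)
    mu_range: List[float] = Field(default_factory=lambda: [0.0, 10.0])
    output_dir: str = "octatten_out"
    seed: int = 0
    log_level: str = "INFO"

    @field_validator("methods")
    @classmethod
    def _check_methods(cls, v: List[str]) -> List[str]:
        for m in v:
            if m.upper() not in ("FD", "LF", "EF"):
                raise ValueError(f"unknown method {m!r}")
        return [m.upper() for m in v]


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw or {})


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _map_config(config: RunConfig, method: str) -> MapConfig:
    return MapConfig(
        method=method,
        data_length_mm=config.data_length_mm,
        averaging=AveragingSpec(
            window_alines=config.averaging.window, step_alines=config.averaging.step
        ),
        surface=SurfaceParams(
            smooth_px=config.surface.smooth_px,
            k_sd=config.surface.k_sd,
            noise_region_px=config.surface.noise_region_px,
        ),
        harmonics=tuple(config.estimator.harmonics),
        inversion=config.estimator.inversion,
        ef_mu_max=config.estimator.ef_mu_max,
    )


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Read inputs, build one map per method, compare, render, manifest.

    Returns a dict of artifact paths and summary numbers.  Per-stage
    wall times land in the manifest under ``runtime`` (alongside the
    timestamp), so byte-level comparisons of manifests can drop that
    one key.
    """
    # fail fast on missing inputs before any heavy I/O or computation
    for label, p in (("volume", config.volume), ("reference", config.reference)):
        if not Path(p).exists():
            raise FileNotFoundError(f"{label} file not found: {p}")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: Dict[str, float] = {}

    t0 = time.perf_counter()
    volume = read_volume(config.volume, config.sidecar)
    reference = read_reference(config.reference)
    timings["read_s"] = time.perf_counter() - t0

    rule = ClassificationRule(
        threshold_mm1=config.classification.threshold_mm1,
        band_threshold_mm1=config.classification.band_threshold_mm1,
    )
    maps: Dict[str, AttenuationMap] = {}
    artifacts: Dict[str, object] = {}
    for method in config.methods:
        t0 = time.perf_counter()
        amap = build_map(volume, reference, _map_config(config, method))
        timings[f"map_{method}_s"] = time.perf_counter() - t0
        maps[method] = amap
        paths = render(
            amap, rule, out_dir / f"map_{method}", mu_range=tuple(config.mu_range)
        )
        artifacts[f"map_{method}_png"] = str(paths["png"])
        artifacts[f"map_{method}_csv"] = str(paths["csv"])

    comparisons = []
    methods = list(maps)
    for i in range(len(methods)):
        for j in range(i + 1, len(methods)):
            a, b = methods[i], methods[j]
            mean_d, sd_d = compare_maps(maps[a], maps[b])
            comparisons.append(
                {"a": a, "b": b, "mean_delta_mm1": mean_d, "sd_delta_mm1": sd_d}
            )
    if comparisons:
        import pandas as pd

        cmp_path = out_dir / "comparisons.csv"
        pd.DataFrame(comparisons).to_csv(cmp_path, index=False, float_format="%.6g")
        artifacts["comparisons_csv"] = str(cmp_path)

    manifest = {
        "package": "octatten",
        "version": __version__,
        "config": config.model_dump(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "library_versions": {
            "numpy": np.__version__,
            "tifffile": tifffile.__version__,
        },
        "comparisons": comparisons,
        "runtime": {
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "timings": timings,
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = str(manifest_path)
    artifacts["comparisons"] = comparisons
    artifacts["maps"] = maps
    return artifacts


def write_ground_truth(mu_truth: np.ndarray, dx: float, dy: float, path) -> Path:
    """Write a ground-truth attenuation grid as CSV (x_mm, y_mm, mu_mm1)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n_frames, n_alines = mu_truth.shape
    lines = ["x_mm,y_mm,mu_mm1"]
    for f in range(n_frames):
        for a in range(n_alines):
            lines.append(f"{a * dx:.6g},{f * dy:.6g},{mu_truth[f, a]:.6g}")
    path.write_text("\n".join(lines) + "\n")
    return path
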