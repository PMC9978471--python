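"""File formats, run configuration and the end-to-end pipeline.

Stacks travel as multi-page TIFF with a JSON sidecar holding the acquisition
metadata (frame rate, pixel size, wavelength, NA) and, for simulated data,
the seed, motion program and ground-truth trace.  Velocity stacks are stored
as a 32-bit float TIFF (mm/s, masked pixels as 0), a companion uint8 mask
TIFF and a JSON sidecar with the timestamps — the mask, not the zeros, is
authoritative.  Metric tables are plain CSV.

Every artifact sidecar carries provenance: package version, seed and the
SHA-256 hash of the resolved run configuration, so a run can be reproduced
from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .beat import roi_waveform, summarize_beat
from .piv import build_grid, ensemble_piv, phase_resolved_piv, vectors_to_velocity
from .speckle_sim import GroundTruthTrace, MotionProgram, ScattererField, SimConfig, simulate_stack
from .velocimetry import SpeckleStack, VelocityStack, velocity_map_stack

__all__ = [
    "AcquisitionMetadata",
    "read_stack",
    "write_stack",
    "read_velocity_stack",
    "write_velocity_stack",
    "load_config",
    "validate_config",
    "demo_config",
    "run_pipeline",
]


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Camera and optics parameters attached to a raw stack."""

    frame_rate: float
    camera_pixel_size: float  # um on the sensor
    magnification: float
    wavelength: float  # nm
    detection_na: float

    def __post_init__(self) -> None:
        for name in dataclasses.fields(self):
            if getattr(self, name.name) <= 0:
                raise ValueError(f"{name.name} must be positive")

    @property
    def effective_pixel_size(self) -> float:
        """Object-space pixel pitch in micrometres."""
        return self.camera_pixel_size / self.magnification

    REQUIRED = ("frame_rate", "camera_pixel_size", "magnification", "wavelength", "detection_na")

    @classmethod
    def from_mapping(cls, data: dict) -> "AcquisitionMetadata":
        missing = [k for k in cls.REQUIRED if k not in data]
        if missing:
            raise ValueError(f"metadata is missing required fields: {', '.join(missing)}")
        return cls(**{k: float(data[k]) for k in cls.REQUIRED})


def _sidecar_path(path: Union[str, Path], explicit: Optional[Union[str, Path]]) -> Path:
    if explicit is not None:
        return Path(explicit)
    return Path(path).with_suffix(".json")


def _load_mapping(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def read_stack(path: Union[str, Path], metadata_path: Optional[Union[str, Path]] = None) -> SpeckleStack:
    """Read a multi-page TIFF plus its JSON/YAML metadata sidecar.

    Raises a ValueError listing any missing metadata fields; ragged pages
    are rejected by the shape check in :class:`SpeckleStack`.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta_file = _sidecar_path(path, metadata_path)
    if not meta_file.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {meta_file}")
    meta = AcquisitionMetadata.from_mapping(_load_mapping(meta_file))
    return SpeckleStack(
        frames=np.asarray(frames),
        frame_rate=meta.frame_rate,
        effective_pixel_size=meta.effective_pixel_size,
        wavelength=meta.wavelength,
        detection_na=meta.detection_na,
    )


def write_stack(
    stack: SpeckleStack,
    path: Union[str, Path],
    metadata_path: Optional[Union[str, Path]] = None,
    dtype: str = "uint16",
    extra_metadata: Optional[dict] = None,
) -> Path:
    """Write a stack as multi-page TIFF (uint16 by default, float32 optional)
    with a JSON metadata sidecar.  uint16 data round-trips bit-exactly;
    float frames destined for uint16 are scaled to the full range."""
    path = Path(path)
    frames = stack.frames
    if dtype == "uint16":
        if frames.dtype != np.uint16:
            peak = float(frames.max())
            scaled = frames / peak * 65535.0 if peak > 0 else frames
            frames = np.round(scaled).astype(np.uint16)
    elif dtype == "float32":
        frames = frames.astype(np.float32)
    else:
        raise ValueError("dtype must be 'uint16' or 'float32'")
    tifffile.imwrite(path, frames)
    # magnification 1: effective pixel size is stored directly
    meta = {
        "frame_rate": stack.frame_rate,
        "camera_pixel_size": stack.effective_pixel_size,
        "magnification": 1.0,
        "wavelength": stack.wavelength,
        "detection_na": stack.detection_na,
        "version": __version__,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    meta_file = _sidecar_path(path, metadata_path)
    meta_file.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def write_velocity_stack(vstack: VelocityStack, path_base: Union[str, Path]) -> dict[str, Path]:
    """Write speeds (float32 TIFF, masked=0), mask (uint8 TIFF) and sidecar.

    The speeds file is guaranteed NaN-free; reconstruction uses the mask.
    """
    base = Path(path_base)
    speeds_path = base.with_name(base.name + "_speeds.tif")
    mask_path = base.with_name(base.name + "_mask.tif")
    sidecar = base.with_name(base.name + "_velocity.json")
    speeds = np.where(vstack.valid, vstack.speeds, 0.0).astype(np.float32)
    tifffile.imwrite(speeds_path, speeds)
    tifffile.imwrite(mask_path, vstack.valid.astype(np.uint8))
    sidecar.write_text(
        json.dumps(
            {
                "timestamps": [float(t) for t in vstack.timestamps],
                "window_frames": int(vstack.window_frames),
                "stride_frames": int(vstack.stride_frames),
                "frame_rate": float(vstack.frame_rate),
                "effective_pixel_size": float(vstack.effective_pixel_size),
                "units": "mm/s",
                "version": __version__,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return {"speeds": speeds_path, "mask": mask_path, "sidecar": sidecar}


def read_velocity_stack(path_base: Union[str, Path]) -> VelocityStack:
    """Inverse of :func:`write_velocity_stack` (lossless up to float32)."""
    base = Path(path_base)
    speeds = tifffile.imread(base.with_name(base.name + "_speeds.tif")).astype(np.float64)
    valid = tifffile.imread(base.with_name(base.name + "_mask.tif")).astype(bool)
    meta = json.loads(base.with_name(base.name + "_velocity.json").read_text())
    speeds = np.where(valid, speeds, np.nan)
    if speeds.ndim == 2:
        speeds = speeds[None]
        valid = valid[None]
    return VelocityStack(
        speeds=speeds,
        timestamps=np.asarray(meta["timestamps"]),
        window_frames=meta["window_frames"],
        stride_frames=meta["stride_frames"],
        valid=valid,
        frame_rate=meta.get("frame_rate", 0.0),
        effective_pixel_size=meta.get("effective_pixel_size", 0.0),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_CONFIG_SCHEMA: dict[str, set[str]] = {
    "simulate": {
        "motion", "speed_power", "speed_recovery", "beat_frequency", "power_fraction",
        "direction_power", "diffusion_coefficient", "n_frames", "frame_rate",
        "shape", "density", "psf_radius", "effective_pixel_size", "wavelength",
        "detection_na", "noise_model", "noise_param", "dephasing",
    },
    "velocity": {"window", "stride", "max_lag", "noise_floor", "n_exponent"},
    "beat": {"roi", "dc_cutoff_hz", "prominence_frac", "min_separation_frac"},
    "piv": {"window", "step", "phase_intervals", "peak_ratio_threshold", "units"},
    "output": {"directory", "prefix"},
}
_TOP_LEVEL = set(_CONFIG_SCHEMA) | {"seed", "stages", "input"}


def validate_config(config: dict) -> dict:
    """Reject unknown keys anywhere in the config; returns the config."""
    unknown = set(config) - _TOP_LEVEL
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for section, keys in _CONFIG_SCHEMA.items():
        sub = config.get(section)
        if sub is None:
            continue
        bad = set(sub) - keys
        if bad:
            raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
    stages = config.get("stages", [])
    known_stages = {"simulate", "velocity", "beat", "piv"}
    if set(stages) - known_stages:
        raise ValueError(f"unknown stages: {sorted(set(stages) - known_stages)}")
    return config


def load_config(path: Union[str, Path]) -> dict:
    return validate_config(yaml.safe_load(Path(path).read_text()))


def demo_config(seed: int = 0) -> dict:
    """Bundled demonstration: a 5 Hz beating patch pushed end to end."""
    return {
        "seed": seed,
        "stages": ["simulate", "velocity", "beat", "piv"],
        "simulate": {
            "motion": "beating",
            "beat_frequency": 5.0,
            "speed_power": 250.0,
            "speed_recovery": 150.0,
            "power_fraction": 0.4,
            "n_frames": 6000,
            "frame_rate": 3000.0,
            "shape": [24, 24],
            "density": 30.0,
        },
        "velocity": {"window": 20, "stride": 10},
        "beat": {"dc_cutoff_hz": 0.5},
        "piv": {"window": 8, "step": 4},
    }


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict, outdir: Union[str, Path]) -> dict[str, Any]:
    """Execute the requested stages (simulate -> velocity -> beat -> piv).

    Identical config + seed produce byte-identical artifacts.  Each stage
    failure aborts with the stage name prepended to the cause.
    """
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", ["simulate", "velocity", "beat"])
    provenance = {"config_hash": _config_hash(config), "seed": seed, "version": __version__}
    artifacts: dict[str, Any] = {"provenance": provenance}

    stack: Optional[SpeckleStack] = None
    trace: Optional[GroundTruthTrace] = None
    try:
        if "simulate" in stages:
            sim = dict(config.get("simulate", {}))
            shape = tuple(sim.pop("shape", (24, 24)))
            density = float(sim.pop("density", 30.0))
            motion_kind = sim.pop("motion", "beating")
            motion_kwargs = {
                k: sim.pop(k)
                for k in (
                    "speed_power", "speed_recovery", "beat_frequency",
                    "power_fraction", "direction_power", "diffusion_coefficient",
                )
                if k in sim
            }
            if motion_kind == "uniform_translation":
                motion = MotionProgram.uniform(
                    motion_kwargs.pop("speed_power", 100.0),
                    tuple(motion_kwargs.pop("direction_power", (-1.0, 0.0))),
                )
            elif motion_kind == "static":
                motion = MotionProgram.static()
            elif motion_kind == "brownian":
                motion = MotionProgram.brownian(motion_kwargs.pop("diffusion_coefficient", 1.0))
            else:
                if "direction_power" in motion_kwargs:
                    motion_kwargs["direction_power"] = tuple(motion_kwargs["direction_power"])
                motion = MotionProgram.beating(**motion_kwargs)
            cfg = SimConfig.from_pixels(shape, seed=seed, **sim)
            fld = ScattererField.random(cfg.field_extent, density, np.random.default_rng(seed))
            stack, trace = simulate_stack(fld, motion, cfg)
            raw_path = outdir / "raw_stack.tif"
            write_stack(
                stack,
                raw_path,
                dtype="float32",
                extra_metadata={
                    "seed": seed,
                    "motion": dataclasses.asdict(motion),
                    "ground_truth": {
                        "times": trace.times.tolist(),
                        "speeds": trace.speeds.tolist(),
                        "directions": trace.directions.tolist(),
                    },
                    **provenance,
                },
            )
            artifacts["raw_stack"] = raw_path
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    if stack is None and ("velocity" in stages or "piv" in stages):
        inp = config.get("input")
        if inp is None:
            raise RuntimeError("stage 'velocity' failed: no input stack and no simulate stage")
        stack = read_stack(inp)

    vstack: Optional[VelocityStack] = None
    if "velocity" in stages:
        try:
            vel = config.get("velocity", {})
            vstack = velocity_map_stack(
                stack,
                window_frames=int(vel.get("window", 20)),
                stride_frames=int(vel.get("stride", 10)),
                max_lag_frames=vel.get("max_lag"),
                noise_floor=float(vel.get("noise_floor", 0.05)),
                n_exponent=float(vel.get("n_exponent", 1.0)),
            )
            artifacts.update(write_velocity_stack(vstack, outdir / "velocity"))
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'velocity' failed: {exc}") from exc

    if "beat" in stages:
        try:
            if vstack is None:
                raise ValueError("beat stage requires the velocity stage")
            b = config.get("beat", {})
            roi = tuple(b["roi"]) if "roi" in b else None
            wf = roi_waveform(vstack, roi=roi)
            summary = summarize_beat(
                wf,
                dc_cutoff_hz=float(b.get("dc_cutoff_hz", 0.5)),
                prominence_frac=float(b.get("prominence_frac", 0.25)),
                min_separation_frac=float(b.get("min_separation_frac", 0.25)),
            )
            wf_path = outdir / "waveform.csv"
            pd.DataFrame({"time_s": wf.times, "value": wf.values}).to_csv(wf_path, index=False)
            from .beat import cbf_fft  # local import keeps module load light

            _, (freqs, amps) = cbf_fft(wf, dc_cutoff_hz=float(b.get("dc_cutoff_hz", 0.5)))
            spec_path = outdir / "spectrum.csv"
            pd.DataFrame({"frequency_hz": freqs, "amplitude": amps}).to_csv(spec_path, index=False)
            summary_path = outdir / "beat_summary.json"
            summary_path.write_text(
                json.dumps({**summary.as_dict(), **provenance}, indent=2, sort_keys=True)
            )
            row_path = outdir / "beat_summary.csv"
            pd.DataFrame([summary.as_dict()]).to_csv(row_path, index=False)
            artifacts.update(
                {"waveform": wf_path, "spectrum": spec_path,
                 "beat_summary": summary_path, "beat_row": row_path}
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'beat' failed: {exc}") from exc

    if "piv" in stages:
        try:
            p = config.get("piv", {})
            grid = build_grid(stack.frames.shape[1:], int(p.get("window", 8)), int(p.get("step", 4)))
            intervals = p.get("phase_intervals")
            if intervals:
                fields = phase_resolved_piv(stack, grid, [tuple(iv) for iv in intervals])
            else:
                fields = [ensemble_piv(stack, grid)]
            if p.get("units") == "um_s":
                fields = [
                    vectors_to_velocity(f, stack.effective_pixel_size, stack.frame_rate)
                    for f in fields
                ]
            piv_paths = []
            for i, f in enumerate(fields):
                centers = f.grid.centers
                df = pd.DataFrame(
                    {
                        "center_row": centers[:, 0],
                        "center_col": centers[:, 1],
                        "u": f.u.ravel(),
                        "v": f.v.ravel(),
                        "peak_quality": f.peak_quality.ravel(),
                        "valid": f.valid.ravel(),
                    }
                )
                path = outdir / f"piv_field_{i}.csv"
                df.to_csv(path, index=False)
                piv_paths.append(path)
            (outdir / "piv_meta.json").write_text(
                json.dumps(
                    {"window": grid.window_size, "step": grid.step,
                     "units": fields[0].units, **provenance},
                    indent=2, sort_keys=True,
                )
            )
            artifacts["piv_fields"] = piv_paths
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'piv' failed: {exc}") from exc

    return artifacts
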