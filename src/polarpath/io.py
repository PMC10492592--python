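"""Configuration files, result containers and CSV/TIFF export.

Config files are flat ``key = value`` text (``#`` comments allowed); every key
is validated against a per-command schema, unknown keys are rejected, and
missing keys fall back to documented defaults.  Simulation results travel in a
single HDF5 container holding the four analyzer-channel images, the
bookkeeping images and a JSON metadata echo of the full configuration, so any
figure-like artifact can be regenerated from the container alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable, Dict, Mapping, Optional, Tuple

import h5py
import numpy as np

from .mie import MieParameters
from .montecarlo import (
    CHANNELS,
    RESULT_FORMAT_VERSION,
    BeamSpec,
    DetectorConfig,
    MediumSpec,
    SimulationResult,
)
from .toothstats import TOOTH_CHANNELS, ToothImageSet, SyntheticToothConfig
from .spatial import ImageGeometry

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "save_config",
    "write_result",
    "read_result",
    "export_tiff",
    "write_tooth_set",
    "read_tooth_set",
    "CONFIG_SCHEMAS",
]


class ConfigError(ValueError):
    """Raised for unparseable, unknown or invalid configuration entries."""


def _positive(key: str) -> Callable[[float], None]:
    def check(value: float) -> None:
        if not value > 0:
            raise ConfigError(f"{key} must be > 0")

    return check


def _non_negative(key: str) -> Callable[[float], None]:
    def check(value: float) -> None:
        if value < 0:
            raise ConfigError(f"{key} must be >= 0")

    return check


def _choice(key: str, options: Tuple[str, ...]) -> Callable[[str], None]:
    def check(value: str) -> None:
        if value not in options:
            raise ConfigError(f"{key} must be one of {options}")

    return check


@dataclass(frozen=True)
class FieldSpec:
    type: type
    default: Any = None
    required: bool = False
    validator: Optional[Callable[[Any], None]] = None


def _f(key, default=None, required=False, positive=False, nonneg=False):
    val = _positive(key) if positive else (_non_negative(key) if nonneg else None)
    return FieldSpec(float, default, required, val)


def _i(key, default=None, required=False, positive=False):
    return FieldSpec(int, default, required, _positive(key) if positive else None)


CONFIG_SCHEMAS: Dict[str, Dict[str, FieldSpec]] = {
    "mie_profile": {
        "wavelength_nm": _f("wavelength_nm", 635.0, positive=True),
        "host_index": _f("host_index", 1.33, positive=True),
        "sphere_index": _f("sphere_index", 1.59, positive=True),
        "diameter_um": _f("diameter_um", 1.04, positive=True),
        "angle_resolution_deg": _f("angle_resolution_deg", 0.25, positive=True),
        "incident_state": FieldSpec(
            str,
            "linear45",
            validator=_choice("incident_state", ("linear45", "circular")),
        ),
    },
    "simulate": {
        "wavelength_nm": _f("wavelength_nm", 635.0, positive=True),
        "host_index": _f("host_index", 1.33, positive=True),
        "sphere_index": _f("sphere_index", 1.59, positive=True),
        "diameter_um": _f("diameter_um", 1.04, positive=True),
        "mus_per_cm": _f("mus_per_cm", 25.0, positive=True),
        "mua_per_cm": _f("mua_per_cm", 0.0, nonneg=True),
        "box_cm": _f("box_cm", 2.2, positive=True),
        "beam_mm": _f("beam_mm", 3.0, positive=True),
        "incident_state": FieldSpec(
            str,
            "linear_minus45",
            validator=_choice(
                "incident_state",
                ("linear_minus45", "linear_plus45", "circular_right", "circular_left"),
            ),
        ),
        "nx": _i("nx", 101, positive=True),
        "ny": _i("ny", 101, positive=True),
        "field_mm": _f("field_mm", 20.0, positive=True),
        "acceptance_deg": _f("acceptance_deg", 15.0, positive=True),
        "n_packets": _i("n_packets", 1_000_000, positive=True),
        "max_events": _i("max_events", 100_000, positive=True),
        "seed": _i("seed", 0),
    },
    "roi": {
        "disc_diameter_mm": _f("disc_diameter_mm", 3.0, positive=True),
        "rect_length_mm": _f("rect_length_mm", 20.0, positive=True),
        "rect_width_mm": _f("rect_width_mm", 1.5, positive=True),
        "rect_angle_deg": _f("rect_angle_deg", 90.0),
        "annulus_inner_mm": _f("annulus_inner_mm", 2.0, nonneg=True),
        "annulus_outer_mm": _f("annulus_outer_mm", 6.0, positive=True),
        "min_photons": _f("min_photons", 5.0, nonneg=True),
    },
    "synth": {
        "n_samples": _i("n_samples", 7, positive=True),
        "spots_per_side": _i("spots_per_side", 2, positive=True),
        "nx": _i("nx", 64, positive=True),
        "field_mm": _f("field_mm", 10.0, positive=True),
        "core_sigma_mm": _f("core_sigma_mm", 1.0, positive=True),
        "background_sigma_mm": _f("background_sigma_mm", 4.0, positive=True),
        "co_linear_amplitude": _f("co_linear_amplitude", 1000.0, positive=True),
        "cross_circular_amplitude": _f("cross_circular_amplitude", 800.0, positive=True),
        "co_linear_background": _f("co_linear_background", 250.0, nonneg=True),
        "cross_circular_background": _f("cross_circular_background", 200.0, nonneg=True),
        "reduction_factor": _f("reduction_factor", 0.6, positive=True),
        "background_reduction": _f("background_reduction", 1.0, positive=True),
        "heterogeneity_scale": _f("heterogeneity_scale", 0.15, nonneg=True),
        "noise_scale": _f("noise_scale", 2.0, nonneg=True),
        "seed": _i("seed", 0),
    },
}


@dataclass(frozen=True)
class RunConfig:
    """A validated, fully defaulted configuration for one command."""

    schema: str
    values: Dict[str, Any]

    def __getitem__(self, key: str) -> Any:
        return self.values[key]


def _parse_flat_file(path) -> Dict[str, str]:
    raw: Dict[str, str] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ConfigError(f"line {lineno}: expected 'key = value'")
        key, value = (part.strip() for part in stripped.split("=", 1))
        if not key:
            raise ConfigError(f"line {lineno}: empty key")
        if key in raw:
            raise ConfigError(f"line {lineno}: duplicate key {key!r}")
        raw[key] = value
    return raw


def load_config(path, schema: str) -> RunConfig:
    """Load and validate a flat key=value config against a named schema.

    Unknown keys are rejected; validation errors name the offending key.
    """
    if schema not in CONFIG_SCHEMAS:
        raise ConfigError(f"unknown schema {schema!r}")
    spec = CONFIG_SCHEMAS[schema]
    raw = _parse_flat_file(path)
    unknown = sorted(set(raw) - set(spec))
    if unknown:
        raise ConfigError(f"unknown key(s) for {schema}: {', '.join(unknown)}")
    values: Dict[str, Any] = {}
    for key, fs in spec.items():
        if key in raw:
            try:
                value = fs.type(raw[key])
            except ValueError as exc:
                raise ConfigError(f"{key}: cannot parse {raw[key]!r} as {fs.type.__name__}") from exc
        elif fs.required:
            raise ConfigError(f"missing required key {key}")
        else:
            value = fs.default
        if fs.validator is not None and value is not None:
            fs.validator(value)
        values[key] = value
    return RunConfig(schema=schema, values=values)


def save_config(config: RunConfig, path) -> None:
    """Write a config back to flat key=value text (round-trips via load_config)."""
    lines = [f"{key} = {value}" for key, value in config.values.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def simulation_inputs_from_config(cfg: RunConfig):
    """(MediumSpec, BeamSpec, DetectorConfig, n_packets, seed, max_events)."""
    v = cfg.values
    mie = MieParameters(
        wavelength_nm=v["wavelength_nm"],
        host_index=v["host_index"],
        sphere_index=v["sphere_index"],
        diameter_um=v["diameter_um"],
    )
    medium = MediumSpec(
        mie=mie,
        mus_per_cm=v["mus_per_cm"],
        mua_per_cm=v["mua_per_cm"],
        box_cm=(v["box_cm"], v["box_cm"], v["box_cm"]),
    )
    beam = BeamSpec(diameter_mm=v["beam_mm"], incident_state=v["incident_state"])
    det = DetectorConfig(
        nx=v["nx"], ny=v["ny"], field_mm=v["field_mm"], acceptance_deg=v["acceptance_deg"]
    )
    return medium, beam, det, v["n_packets"], v["seed"], v["max_events"]


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------


def write_result(path, result: SimulationResult) -> None:
    """Write a SimulationResult to an HDF5 container (lossless round-trip)."""
    meta = {
        "launched": result.launched,
        "detected": result.detected,
        "missed": result.missed,
        "capped": result.capped,
        "seed": result.seed,
        "pol_axis_deg": result.pol_axis_deg,
        "detector": {
            "nx": result.detector.nx,
            "ny": result.detector.ny,
            "field_mm": result.detector.field_mm,
            "acceptance_deg": result.detector.acceptance_deg,
        },
        "medium": result.medium_echo,
        "beam": result.beam_echo,
    }
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = result.format_version
        f.attrs["metadata_json"] = json.dumps(meta)
        grp = f.create_group("channels")
        nsc = f.create_group("channel_nscatter")
        for name in CHANNELS:
            grp.create_dataset(name, data=result.channels[name])
            nsc.create_dataset(name, data=result.channel_nscatter[name])
        f.create_dataset("photon_count", data=result.photon_count)
        f.create_dataset("nscatter_total", data=result.nscatter_total)
        f.create_dataset("pathlength_total", data=result.pathlength_total)


def read_result(path) -> SimulationResult:
    """Read a SimulationResult container written by :func:`write_result`."""
    with h5py.File(path, "r") as f:
        if "metadata_json" not in f.attrs:
            raise IOError("not a polarpath result container (missing metadata)")
        meta = json.loads(f.attrs["metadata_json"])
        channels = {}
        channel_nscatter = {}
        for name in CHANNELS:
            if name not in f["channels"]:
                raise IOError(f"container is missing channel {name!r}")
            channels[name] = f["channels"][name][...]
            channel_nscatter[name] = f["channel_nscatter"][name][...]
        det = DetectorConfig(**meta["detector"])
        return SimulationResult(
            channels=channels,
            channel_nscatter=channel_nscatter,
            photon_count=f["photon_count"][...],
            nscatter_total=f["nscatter_total"][...],
            pathlength_total=f["pathlength_total"][...],
            launched=int(meta["launched"]),
            detected=int(meta["detected"]),
            missed=int(meta["missed"]),
            capped=int(meta["capped"]),
            seed=int(meta["seed"]),
            pol_axis_deg=float(meta["pol_axis_deg"]),
            detector=det,
            medium_echo=meta["medium"],
            beam_echo=meta["beam"],
            format_version=str(f.attrs["format_version"]),
        )


def export_tiff(result: SimulationResult, directory) -> None:
    """Export the channel and bookkeeping images as 32-bit TIFFs."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in CHANNELS:
        tifffile.imwrite(
            directory / f"{name}.tif", result.channels[name].astype(np.float32)
        )
    tifffile.imwrite(
        directory / "photon_count.tif", result.photon_count.astype(np.float32)
    )
    tifffile.imwrite(
        directory / "nscatter_total.tif", result.nscatter_total.astype(np.float32)
    )


def write_tooth_set(path, image_set: ToothImageSet) -> None:
    """Write a synthetic tooth image set to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = RESULT_FORMAT_VERSION
        geom = image_set.geometry
        f.attrs["geometry_json"] = json.dumps(
            {
                "nx": geom.nx,
                "ny": geom.ny,
                "field_mm": geom.field_mm,
                "pol_axis_deg": geom.pol_axis_deg,
            }
        )
        grp = f.create_group("images")
        for (sample, side, spot, channel), img in image_set.images.items():
            grp.create_dataset(f"{sample}/{side}/{spot}/{channel}", data=img)


def read_tooth_set(path) -> ToothImageSet:
    """Read a tooth image set container written by :func:`write_tooth_set`."""
    with h5py.File(path, "r") as f:
        if "geometry_json" not in f.attrs:
            raise IOError("not a polarpath tooth-set container")
        g = json.loads(f.attrs["geometry_json"])
        geom = ImageGeometry(**g)
        images = {}
        grp = f["images"]
        for sample in grp:
            for side in grp[sample]:
                for spot in grp[sample][side]:
                    for channel in grp[sample][side][spot]:
                        images[(sample, side, int(spot), channel)] = grp[sample][side][
                            spot
                        ][channel][...]
        return ToothImageSet(
            geometry=geom, images=images, config=SyntheticToothConfig()
        )
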