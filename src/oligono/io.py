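"""File I/O: TIFF stacks with sidecar metadata, time-course CSV, config JSON.

TIFF is the sole image format. Channel labels, pixel calibration and axis
order live in a sidecar JSON next to the TIFF (``<stem>.meta.json``) rather
than in TIFF tags, which keeps the files readable by any dialect. Kinetics
trajectories are written as plain CSV (``time_s,donor_M,no_M``) with nine
significant digits. Every CLI run writes a provenance record (config echo +
package version) next to its outputs.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import tifffile

from . import __version__
from .colocalization import ImageStack
from .errors import InvalidParameterError
from .kinetics import DonorSpec, MediumSpec, NOTimeCourse, VesselSpec
from .morphometry import FieldImage

__all__ = [
    "read_stack",
    "write_stack",
    "read_field",
    "write_timecourse",
    "read_timecourse",
    "write_ground_truth",
    "load_scenario",
    "write_provenance",
]

_CANONICAL_AXES = "CZYX"


def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/expand an array with declared axes to (C, Z, Y, X)."""
    axes = axes.upper()
    if sorted(axes) != sorted(set(axes)) or any(a not in _CANONICAL_AXES for a in axes):
        raise InvalidParameterError(f"axes must be a subset of CZYX without repeats, got {axes!r}")
    if data.ndim != len(axes):
        raise InvalidParameterError(
            f"declared axes {axes!r} do not match array rank {data.ndim}"
        )
    for missing in _CANONICAL_AXES:
        if missing not in axes:
            data = np.expand_dims(data, 0)
            axes = missing + axes
    return np.transpose(data, [axes.index(a) for a in _CANONICAL_AXES])


def read_stack(
    path,
    axes: str | None = None,
    channel_labels: list[str] | None = None,
    pixel_size: float | None = None,
    z_step: float | None = None,
) -> ImageStack:
    """Read a TIFF into an :class:`ImageStack`, axis order normalized to CZYX.

    Explicit arguments override the sidecar ``<stem>.meta.json``; anything
    still unknown falls back to axes="ZYX"-style inference from rank,
    numbered channel labels and unit pixel calibration.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # malformed file
        raise InvalidParameterError(f"cannot read TIFF {path}: {exc}") from exc
    meta = {}
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    axes = axes or meta.get("axes") or _CANONICAL_AXES[-np.asarray(data).ndim :]
    arr = _normalize_axes(np.asarray(data), axes)
    labels = channel_labels or meta.get("channel_labels") or [
        f"ch{i}" for i in range(arr.shape[0])
    ]
    return ImageStack(
        intensities=arr,
        channel_labels=list(labels),
        pixel_size=pixel_size or meta.get("pixel_size_um") or 1.0,
        z_step=z_step or meta.get("z_step_um") or 1.0,
    )


def write_stack(stack: ImageStack, path) -> Path:
    """Write an :class:`ImageStack` as TIFF plus a metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.intensities), photometric="minisblack")
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "axes": _CANONICAL_AXES,
                "channel_labels": stack.channel_labels,
                "pixel_size_um": stack.pixel_size,
                "z_step_um": stack.z_step,
            },
            indent=2,
        )
    )
    return path


def read_field(path, pixel_size: float | None = None) -> FieldImage:
    """Read a single-channel 2-D TIFF as a :class:`FieldImage`."""
    path = Path(path)
    data = np.asarray(tifffile.imread(path))
    if data.ndim != 2:
        raise InvalidParameterError(f"field TIFF must be 2-D, got {data.ndim}-D")
    meta = {}
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return FieldImage(intensities=data, pixel_size=pixel_size or meta.get("pixel_size_um") or 1.0)


def write_field(field: FieldImage, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(field.intensities))
    path.with_suffix(".meta.json").write_text(
        json.dumps({"pixel_size_um": field.pixel_size}, indent=2)
    )
    return path


def write_timecourse(tc: NOTimeCourse, path) -> Path:
    """Write a trajectory as ``time_s,donor_M,no_M`` CSV, 9 significant digits."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "donor_M", "no_M"])
        for t, d, n in zip(tc.times, tc.donor_conc, tc.no_conc):
            w.writerow([f"{t:.8e}", f"{d:.8e}", f"{n:.8e}"])
    return path


def read_timecourse(path) -> NOTimeCourse:
    """Re-read a trajectory CSV (provenance and dense output are not restored)."""
    data = np.genfromtxt(path, delimiter=",", names=True)
    data = np.atleast_1d(data)
    return NOTimeCourse(
        times=data["time_s"], donor_conc=data["donor_M"], no_conc=data["no_M"]
    )


def write_ground_truth(truth, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=2))
    return path


_SCENARIO_KEYS = {
    "donor": {"name", "initial_conc_M", "half_life_s", "stoichiometry"},
    "medium": {"o2_M", "k_autox", "autox_factor", "k_consume"},
    "vessel": {"kl_cm_s", "well_diameter_cm", "area_cm2", "volume_cm3", "k_out_override"},
    "sim": {"t_end_s", "n_points"},
}


def load_scenario(config: dict) -> tuple[DonorSpec, MediumSpec, VesselSpec, dict]:
    """Validate a kinetic-scenario config tree and build the spec objects.

    Unknown keys anywhere in the tree are rejected rather than ignored, so a
    typo cannot silently fall back to a default.
    """
    unknown = set(config) - set(_SCENARIO_KEYS)
    if unknown:
        raise InvalidParameterError(f"unknown config sections: {sorted(unknown)}")
    for section, allowed in _SCENARIO_KEYS.items():
        extra = set(config.get(section, {})) - allowed
        if extra:
            raise InvalidParameterError(f"unknown keys in {section!r}: {sorted(extra)}")
    d = config.get("donor", {})
    donor = DonorSpec(
        name=d.get("name", "donor"),
        initial_conc=d["initial_conc_M"],
        half_life=d["half_life_s"],
        release_stoichiometry=d.get("stoichiometry", 2.0),
    )
    m = config.get("medium", {})
    medium = MediumSpec(
        **{
            k2: m[k1]
            for k1, k2 in [
                ("o2_M", "o2_conc"),
                ("k_autox", "k_autox"),
                ("autox_factor", "autox_stoich_factor"),
                ("k_consume", "k_consume"),
            ]
            if k1 in m
        }
    )
    v = config.get("vessel", {})
    vessel = VesselSpec(
        volume=v["volume_cm3"],
        kl=v.get("kl_cm_s", VesselSpec.kl),
        area=v.get("area_cm2"),
        well_diameter=v.get("well_diameter_cm"),
        k_out_override=v.get("k_out_override"),
    )
    sim = dict(config.get("sim", {}))
    return donor, medium, vessel, sim


def write_provenance(out_prefix, config: dict) -> Path:
    """Record what produced a set of outputs: config echo + package version."""
    path = Path(str(out_prefix) + ".provenance.json")
    path.write_text(json.dumps({"oligono_version": __version__, "config": config}, indent=2))
    return path
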