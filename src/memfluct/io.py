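"""File formats: multi-page TIFF movies/stacks with JSON sidecars, 2-column
CSV curves, and multi-channel tension-map TIFFs.

Height-mode movies are stored as 32-bit float TIFF; intensity-mode movies as
16-bit unsigned TIFF.  Every TIFF carries a sidecar ``<name>.json`` with
pixel size, frame interval, seed and truth summaries.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import tifffile

from .datatypes import (CorrelationCurve, FluctuationMovie, FluorescenceStack,
                        ScatteringProfile)
from .mechanics import TensionMap, Thresholds

__all__ = [
    "write_movie", "read_movie",
    "write_stack", "read_stack",
    "write_profile_csv", "read_profile_csv",
    "write_curve_csv", "read_curve_csv",
    "write_tension_map", "read_tension_map",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: FluctuationMovie, path) -> Path:
    path = Path(path)
    if movie.units == "au":
        data = np.clip(np.round(movie.values), 0, 65535).astype(np.uint16)
    else:
        data = movie.values.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "units": movie.units,
        "pixel_size_nm": movie.pixel_size,
        "frame_interval_s": movie.frame_interval,
        "seed": movie.seed,
    }
    if movie.truth_tension is not None:
        meta["truth_tension"] = movie.truth_tension.tolist()
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_movie(path) -> FluctuationMovie:
    path = Path(path)
    values = tifffile.imread(path)
    if values.ndim == 2:
        values = values[None]
    meta = json.loads(_sidecar(path).read_text())
    truth = meta.get("truth_tension")
    return FluctuationMovie(
        values=np.asarray(values, dtype=float), units=meta["units"],
        pixel_size=meta["pixel_size_nm"],
        frame_interval=meta["frame_interval_s"], seed=meta.get("seed"),
        truth_tension=np.asarray(truth, dtype=float) if truth is not None else None)


def write_stack(stack: FluorescenceStack, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, stack.values.astype(np.float32), photometric="minisblack")
    meta = {
        "channels": list(stack.channels),
        "pixel_size_xy_um": stack.pixel_size_xy,
        "z_step_um": stack.z_step,
        "truth_overlap_fraction": stack.truth_overlap_fraction,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_stack(path) -> FluorescenceStack:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(_sidecar(path).read_text())
    while values.ndim < 4:
        values = values[None]
    return FluorescenceStack(
        values=values, channels=tuple(meta["channels"]),
        pixel_size_xy=meta["pixel_size_xy_um"], z_step=meta["z_step_um"],
        truth_overlap_fraction=meta.get("truth_overlap_fraction"))


def write_profile_csv(profile: ScatteringProfile, path) -> Path:
    path = Path(path)
    frame = pd.DataFrame({"s_inv_nm": profile.s, "intensity": profile.intensity})
    if profile.sigma_i is not None:
        frame["sigma_i"] = profile.sigma_i
    frame.to_csv(path, index=False, lineterminator="\n")
    return path


def read_profile_csv(path) -> ScatteringProfile:
    frame = pd.read_csv(path)
    sigma_i = frame["sigma_i"].to_numpy() if "sigma_i" in frame else None
    return ScatteringProfile(s=frame["s_inv_nm"].to_numpy(),
                             intensity=frame["intensity"].to_numpy(),
                             sigma_i=sigma_i)


def write_curve_csv(curve: CorrelationCurve, path) -> Path:
    path = Path(path)
    pd.DataFrame({"tau_s": curve.tau, "g": curve.g}).to_csv(
        path, index=False, lineterminator="\n")
    return path


def read_curve_csv(path, label: str = "") -> CorrelationCurve:
    frame = pd.read_csv(path)
    return CorrelationCurve(tau=frame["tau_s"].to_numpy(),
                            g=frame["g"].to_numpy(), label=label)


def write_tension_map(tmap: TensionMap, path) -> Path:
    """Four-channel 32-bit TIFF: sigma, SD_time, r^2, validity mask."""
    path = Path(path)
    channels = np.stack([
        tmap.sigma_map, tmap.sd_time_map, tmap.r2_map,
        tmap.valid_mask.astype(float)]).astype(np.float32)
    tifffile.imwrite(path, channels, photometric="minisblack")
    meta = {
        "channels": ["sigma_pn_per_um", "sd_time_nm", "r_squared", "valid_mask"],
        "thresholds": {
            "r2_min": tmap.thresholds.r2_min,
            "sigma_max": tmap.thresholds.sigma_max,
            "sd_time_max": tmap.thresholds.sd_time_max,
        },
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_tension_map(path) -> TensionMap:
    path = Path(path)
    channels = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(_sidecar(path).read_text())
    t = meta["thresholds"]
    thresholds = Thresholds(r2_min=t["r2_min"], sigma_max=t["sigma_max"],
                            sd_time_max=t["sd_time_max"])
    return TensionMap(sigma_map=channels[0], sd_time_map=channels[1],
                      r2_map=channels[2], valid_mask=channels[3] > 0.5,
                      thresholds=thresholds)
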