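"""Readers and writers for stacks, series, spectra, maps and reports.

On-disk formats: multi-page TIFF (16-bit container for 12-bit raw frames,
float32 for contrast/ratio maps), CSV for per-frame timestamps
(frame_index, wavelength_nm, t_seconds) and for time series / spectra,
JSON for configuration, ground truth and reports.  A sidecar
``<image>.json`` next to a stack carries acquisition metadata (exposure
time, bit depth).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import tifffile

from .datatypes import (
    ContrastMap,
    ContrastSeries,
    GroundTruth,
    PowerSpectrum,
    RateReport,
    SpeckleStack,
)

PathLike = Union[str, Path]


def write_stack(stack: SpeckleStack, image_path: PathLike, timestamp_path: PathLike) -> None:
    """Write one stack as multi-page TIFF plus a timestamp CSV and sidecar."""
    image_path, timestamp_path = Path(image_path), Path(timestamp_path)
    tifffile.imwrite(image_path, stack.frames.astype(np.uint16))
    pd.DataFrame(
        {
            "frame_index": np.arange(stack.n_frames),
            "wavelength_nm": stack.wavelength,
            "t_seconds": stack.timestamps,
        }
    ).to_csv(timestamp_path, index=False)
    sidecar = {
        "exposure_time": stack.exposure_time,
        "bit_depth": stack.bit_depth,
        "wavelength_nm": stack.wavelength,
        "metadata": {k: v for k, v in stack.metadata.items() if _jsonable(v)},
    }
    image_path.with_suffix(image_path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def write_interleaved(
    stacks: Dict[int, SpeckleStack], image_path: PathLike, timestamp_path: PathLike
) -> None:
    """Merge wavelength streams by timestamp into one TIFF + CSV."""
    image_path, timestamp_path = Path(image_path), Path(timestamp_path)
    rows = []
    for wl, st in stacks.items():
        for i in range(st.n_frames):
            rows.append((st.timestamps[i], wl, i))
    rows.sort()
    frames = np.stack([stacks[wl].frames[i] for _, wl, i in rows])
    tifffile.imwrite(image_path, frames.astype(np.uint16))
    pd.DataFrame(
        {
            "frame_index": np.arange(len(rows)),
            "wavelength_nm": [wl for _, wl, _ in rows],
            "t_seconds": [t for t, _, _ in rows],
        }
    ).to_csv(timestamp_path, index=False)
    any_stack = next(iter(stacks.values()))
    sidecar = {
        "exposure_time": any_stack.exposure_time,
        "bit_depth": any_stack.bit_depth,
        "interleaved": True,
    }
    image_path.with_suffix(image_path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def read_stack(
    image_path: PathLike, timestamp_path: PathLike
) -> Dict[int, SpeckleStack]:
    """Read a (possibly interleaved) stack; returns one stack per wavelength.

    The timestamp CSV's wavelength column demultiplexes the pages; per
    stream, timestamps must be strictly increasing.  A sidecar JSON next
    to the image supplies exposure time and bit depth when present.
    """
    image_path, timestamp_path = Path(image_path), Path(timestamp_path)
    frames = tifffile.imread(image_path)
    if frames.ndim == 2:
        frames = frames[None]
    table = pd.read_csv(timestamp_path)
    required = {"frame_index", "wavelength_nm", "t_seconds"}
    if not required.issubset(table.columns):
        raise ValueError(f"timestamp table must have columns {sorted(required)}")
    if len(table) != frames.shape[0]:
        raise ValueError(
            f"page count {frames.shape[0]} != timestamp row count {len(table)}"
        )
    sidecar_path = image_path.with_suffix(image_path.suffix + ".json")
    meta = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    exposure = float(meta.get("exposure_time", np.nan))
    bit_depth = int(meta.get("bit_depth", 16))
    stacks: Dict[int, SpeckleStack] = {}
    for wl, group in table.groupby("wavelength_nm", sort=True):
        try:
            wl_int = int(wl)
        except (TypeError, ValueError):
            raise ValueError(f"unknown wavelength label {wl!r}") from None
        idx = group["frame_index"].to_numpy()
        ts = group["t_seconds"].to_numpy(dtype=float)
        order = np.argsort(idx)
        idx, ts = idx[order], ts[order]
        if np.any(np.diff(ts) <= 0):
            raise ValueError(
                f"timestamps for wavelength {wl_int} nm are not strictly increasing"
            )
        stacks[wl_int] = SpeckleStack(
            frames=frames[idx],
            timestamps=ts,
            wavelength=wl_int,
            exposure_time=exposure,
            bit_depth=bit_depth,
            metadata={"source": str(image_path)},
        )
    return stacks


def write_contrast_map(cmap: ContrastMap, path: PathLike) -> None:
    tifffile.imwrite(Path(path), cmap.values.astype(np.float32))


def write_series(series: ContrastSeries, path: PathLike) -> None:
    pd.DataFrame({"t_seconds": series.t, "contrast": series.k}).to_csv(
        Path(path), index=False
    )


def read_series(path: PathLike) -> ContrastSeries:
    df = pd.read_csv(path)
    if not {"t_seconds", "contrast"}.issubset(df.columns):
        raise ValueError("series CSV needs columns t_seconds, contrast")
    return ContrastSeries(
        t=df["t_seconds"].to_numpy(float), k=df["contrast"].to_numpy(float)
    )


def write_spectrum(spectrum: PowerSpectrum, path: PathLike) -> None:
    pd.DataFrame({"freq_hz": spectrum.freq, "power": spectrum.power}).to_csv(
        Path(path), index=False
    )


def write_rate_report(report: RateReport, path: PathLike) -> None:
    payload = {
        "estimates": [
            {
                "kind": e.kind,
                "frequency_hz": e.frequency,
                "rate_per_min": e.rate,
                "uncertainty_per_min": e.uncertainty,
                "peak_power": e.peak_power,
                "is_primary": e.is_primary,
            }
            for e in report.estimates
        ],
        "skipped_bands": report.skipped_bands,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_ground_truth(truth: GroundTruth, path: PathLike) -> None:
    payload = {
        "seed": truth.seed,
        "params": truth.params.model_dump(),
        "timestamps": truth.timestamps.tolist(),
        "per_frame_tau_c": truth.per_frame_tau_c.tolist(),
        "per_frame_chromophores": truth.per_frame_chromophores.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_manifest(out_dir: PathLike, paths: List[Path], complete: bool = True) -> Path:
    """SHA-256 content manifest of every artifact written by a run."""
    out_dir = Path(out_dir)
    entries = {}
    for p in sorted(paths):
        digest = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        entries[str(Path(p).relative_to(out_dir))] = digest
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps({"complete": complete, "artifacts": entries}, indent=2, sort_keys=True)
    )
    return manifest_path


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
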