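"""Readers and writers for all interchange formats.

Sweeps travel as one delimited-text file each (columns time_s, current_pA,
voltage_mV) plus a JSON manifest describing the cell and its sweep list;
an equivalent single-container HDF5 layout is also supported.  VSDI movies
travel as multi-frame TIFF stacks with a JSON sidecar.  Tables are CSV
with a stable column order, and every output carries the analysis
configuration for provenance.
"""

from __future__ import annotations

import json

from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import AnalysisConfig, DEFAULT_CONFIG
from .exceptions import DimensionMismatchError, ManifestError
from .recording import GENOTYPES, CellRecording, Sweep
from .vsdi import ROISpec, VSDIMovie

PathLike = Union[str, Path]

MANIFEST_SCHEMA_VERSION = 1
SWEEP_COLUMNS = ["time_s", "current_pA", "voltage_mV"]


# ---------------------------------------------------------------------------
# sweeps + manifest
# ---------------------------------------------------------------------------

def write_recording(rec: CellRecording, out_dir: PathLike) -> Path:
    """Write one cell as per-sweep CSV files plus ``manifest.json``.

    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(rec.sweeps):
        name = f"sweep{i:03d}.csv"
        df = pd.DataFrame({
            "time_s": s.time, "current_pA": s.current,
            "voltage_mV": s.voltage,
        })
        df.to_csv(out / name, index=False)
        entries.append({
            "file": name,
            "sweep_kind": s.sweep_kind,
            "sample_rate_hz": s.sample_rate,
            "stim_onset_s": s.stim_onset,
            "stim_offset_s": s.stim_offset,
            "step_amplitude_pA": s.step_amplitude,
        })
    manifest = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "cell_id": rec.cell_id,
        "animal_id": rec.animal_id,
        "genotype": rec.genotype,
        "age_group": rec.age_group,
        "sex": rec.sex,
        "region": rec.region,
        "setup": rec.setup,
        "bridge_balance_MOhm": rec.bridge_balance,
        "sweeps": entries,
    }
    if rec.ground_truth is not None:
        (out / "ground_truth.json").write_text(
            json.dumps(rec.ground_truth, indent=1))
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def _validate_manifest(manifest: dict, base: Path) -> None:
    if manifest.get("schema_version") != MANIFEST_SCHEMA_VERSION:
        raise ManifestError(
            f"unsupported schema version {manifest.get('schema_version')!r}"
        )
    genotype = manifest.get("genotype")
    if genotype not in GENOTYPES:
        raise ManifestError(f"unknown genotype {genotype!r}")
    seen = set()
    for entry in manifest.get("sweeps", []):
        f = base / entry["file"]
        if not f.exists():
            raise ManifestError(f"missing sweep file: {f}")
        if entry["file"] in seen:
            raise ManifestError(f"duplicate sweep file: {entry['file']}")
        seen.add(entry["file"])


def read_sweeps(manifest_path: PathLike) -> CellRecording:
    """Load one CellRecording from a manifest.

    Raises :class:`ManifestError` for missing files or invalid metadata
    and a column error for malformed sweep CSVs.
    """
    path = Path(manifest_path)
    manifest = json.loads(path.read_text())
    base = path.parent
    _validate_manifest(manifest, base)

    sweeps = []
    for entry in manifest["sweeps"]:
        df = pd.read_csv(base / entry["file"])
        missing = [c for c in SWEEP_COLUMNS if c not in df.columns]
        if missing:
            raise ManifestError(
                f"{entry['file']}: missing columns {missing}"
            )
        sweeps.append(Sweep(
            time=df["time_s"].to_numpy(),
            current=df["current_pA"].to_numpy(),
            voltage=df["voltage_mV"].to_numpy(),
            sample_rate=float(entry["sample_rate_hz"]),
            stim_onset=float(entry["stim_onset_s"]),
            stim_offset=float(entry["stim_offset_s"]),
            step_amplitude=float(entry.get("step_amplitude_pA", 0.0)),
            sweep_kind=entry.get("sweep_kind", "step"),
        ))
    gt_path = base / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() \
        else None
    return CellRecording(
        cell_id=manifest["cell_id"],
        animal_id=manifest["animal_id"],
        genotype=manifest["genotype"],
        age_group=manifest.get("age_group", ""),
        sex=manifest.get("sex", ""),
        region=manifest.get("region", "MEC"),
        setup=manifest.get("setup", ""),
        bridge_balance=float(manifest.get("bridge_balance_MOhm",
                                          float("nan"))),
        sweeps=sweeps,
        ground_truth=ground_truth,
    )


def write_recording_h5(rec: CellRecording, path: PathLike) -> Path:
    """Single-container HDF5 layout mirroring the manifest."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.attrs.update({
            "schema_version": MANIFEST_SCHEMA_VERSION,
            "cell_id": rec.cell_id, "animal_id": rec.animal_id,
            "genotype": rec.genotype, "age_group": rec.age_group,
            "sex": rec.sex, "region": rec.region, "setup": rec.setup,
            "bridge_balance_MOhm": rec.bridge_balance,
        })
        for i, s in enumerate(rec.sweeps):
            grp = h5.create_group(f"sweep{i:03d}")
            grp.create_dataset("time_s", data=s.time)
            grp.create_dataset("current_pA", data=s.current)
            grp.create_dataset("voltage_mV", data=s.voltage)
            grp.attrs.update({
                "sweep_kind": s.sweep_kind,
                "sample_rate_hz": s.sample_rate,
                "stim_onset_s": s.stim_onset,
                "stim_offset_s": s.stim_offset,
                "step_amplitude_pA": s.step_amplitude,
            })
    return path


def read_sweeps_h5(path: PathLike) -> CellRecording:
    with h5py.File(Path(path), "r") as h5:
        sweeps = []
        for key in sorted(k for k in h5 if k.startswith("sweep")):
            grp = h5[key]
            sweeps.append(Sweep(
                time=grp["time_s"][()],
                current=grp["current_pA"][()],
                voltage=grp["voltage_mV"][()],
                sample_rate=float(grp.attrs["sample_rate_hz"]),
                stim_onset=float(grp.attrs["stim_onset_s"]),
                stim_offset=float(grp.attrs["stim_offset_s"]),
                step_amplitude=float(grp.attrs["step_amplitude_pA"]),
                sweep_kind=str(grp.attrs["sweep_kind"]),
            ))
        return CellRecording(
            cell_id=str(h5.attrs["cell_id"]),
            animal_id=str(h5.attrs["animal_id"]),
            genotype=str(h5.attrs["genotype"]),
            age_group=str(h5.attrs["age_group"]),
            sex=str(h5.attrs["sex"]),
            region=str(h5.attrs["region"]),
            setup=str(h5.attrs["setup"]),
            bridge_balance=float(h5.attrs["bridge_balance_MOhm"]),
            sweeps=sweeps,
        )


# ---------------------------------------------------------------------------
# VSDI movies
# ---------------------------------------------------------------------------

def write_movie(movie: VSDIMovie, path: PathLike) -> Path:
    """Write a movie as multi-frame TIFF (frame-major) + JSON sidecar."""
    path = Path(path)
    stack = np.moveaxis(np.asarray(movie.frames, dtype=np.float32), 2, 0)
    tifffile.imwrite(path, stack)
    sidecar = {
        "height": movie.frames.shape[0],
        "width": movie.frames.shape[1],
        "n_frames": movie.frames.shape[2],
        "frame_interval_ms": movie.frame_interval_ms,
        "stim_frame": movie.stim_frame,
        "stim_frames": list(movie.stim_frames),
        "n_baseline_frames": movie.n_baseline_frames,
        "trial_id": movie.trial_id,
        "condition": movie.condition,
        "stimulus": movie.stimulus,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_movie(path: PathLike,
               sidecar: Optional[PathLike] = None) -> VSDIMovie:
    """Read a TIFF stack + sidecar; dimensions are cross-checked."""
    path = Path(path)
    sidecar_path = Path(sidecar) if sidecar else path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text())
    stack = tifffile.imread(path)
    if stack.ndim != 3:
        raise DimensionMismatchError("expected a multi-frame stack")
    frames = np.moveaxis(stack, 0, 2)
    expect = (meta["height"], meta["width"], meta["n_frames"])
    if frames.shape != tuple(expect):
        raise DimensionMismatchError(
            f"stack shape {frames.shape} != sidecar {tuple(expect)}"
        )
    return VSDIMovie(
        frames=frames,
        frame_interval_ms=float(meta["frame_interval_ms"]),
        stim_frame=int(meta["stim_frame"]),
        n_baseline_frames=int(meta["n_baseline_frames"]),
        trial_id=str(meta.get("trial_id", "0")),
        condition=meta.get("condition", "normal_ACSF"),
        stimulus=meta.get("stimulus", "single_0.2mA"),
        stim_frames=tuple(meta.get("stim_frames", [meta["stim_frame"]])),
    )


def write_rois(rois: ROISpec, path: PathLike) -> Path:
    path = Path(path)
    payload: dict = {
        "rois": {name: pix.tolist() for name, pix in rois.rois.items()},
    }
    if rois.stripe is not None:
        payload["stripe"] = rois.stripe.tolist()
        payload["stripe_distances"] = np.asarray(
            rois.stripe_distances).tolist()
    if rois.um_per_pixel is not None:
        payload["um_per_pixel"] = rois.um_per_pixel
    path.write_text(json.dumps(payload))
    return path


def read_rois(path: PathLike) -> ROISpec:
    d = json.loads(Path(path).read_text())
    return ROISpec(
        rois={name: np.asarray(pix, dtype=int)
              for name, pix in d.get("rois", {}).items()},
        stripe=(np.asarray(d["stripe"], dtype=int)
                if "stripe" in d else None),
        stripe_distances=(np.asarray(d["stripe_distances"], dtype=float)
                          if "stripe_distances" in d else None),
        um_per_pixel=d.get("um_per_pixel"),
    )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_table(rows: Sequence[dict], path: PathLike,
                config: AnalysisConfig = DEFAULT_CONFIG) -> Path:
    """Feature/quantification table as CSV with a stable column order.

    A sibling ``<name>.provenance.json`` records the configuration and
    software version.
    """
    path = Path(path)
    df = pd.DataFrame(list(rows))
    df.to_csv(path, index=False)
    prov = {"software": f"entophys {__version__}",
            "config": config.to_dict()}
    path.with_suffix(path.suffix + ".provenance.json").write_text(
        json.dumps(prov, indent=1))
    return path
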