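"""On-disk layout of synthetic study datasets and analysis reports.

A dataset directory holds a JSON manifest, per-measurement multi-page TIFF
frame stacks (10-bit data in 16-bit pages) with JSON sidecars, 32-bit float
reference parameter TIFFs, per-(parameter, distance) white/dark reference
frames, and per-band static SNR acquisition stacks.  Everything written here
is re-readable by :func:`read_dataset`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .acquisition import IlluminationSequence, RawFrame, Slot
from .phantom import (
    Measurement,
    OcclusionProtocol,
    ReferenceImage,
    StudyDataset,
    StudyDesign,
)

__all__ = [
    "sequence_to_dict",
    "sequence_from_dict",
    "write_dataset",
    "read_dataset",
    "write_analysis",
]


def sequence_to_dict(seq: IlluminationSequence) -> dict:
    return {
        "slots": [[[eid, on] for eid, on in slot.emitters] for slot in seq.slots],
        "loop": seq.loop,
    }


def sequence_from_dict(d: dict) -> IlluminationSequence:
    return IlluminationSequence(
        [Slot([(eid, on) for eid, on in slot]) for slot in d["slots"]],
        loop=d.get("loop", True),
    )


def _write_frames(path: Path, frames: Sequence[RawFrame], sidecar: dict | None = None) -> None:
    stack = np.stack([f.pixels.astype(np.uint16) for f in frames])
    tifffile.imwrite(path, stack)
    meta = {
        "image_indexes": [f.image_index for f in frames],
        "frame_numbers": [f.frame_number for f in frames],
        "bit_depth": 10,
    }
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def _read_frames(path: Path) -> list[RawFrame]:
    stack = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return [
        RawFrame(pixels=stack[i], image_index=idx, frame_number=num)
        for i, (idx, num) in enumerate(zip(meta["image_indexes"], meta["frame_numbers"]))
    ]


def _measurement_dirname(m: Measurement) -> str:
    return f"{m.parameter}_{m.distance_mm:g}mm_{m.participant_id}_b{m.minute:02d}"


def write_dataset(dataset: StudyDataset, out_dir: str | Path, dry_run: bool = False) -> Path:
    """Write a study dataset; with ``dry_run`` only the manifest is written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = dataset.manifest()
    records = []
    for m in dataset.measurements:
        name = _measurement_dirname(m)
        records.append(
            {
                "id": name,
                "parameter": m.parameter,
                "msi_parameter": m.msi_parameter,
                "participant_id": m.participant_id,
                "sex": m.sex,
                "age": m.age,
                "distance_mm": m.distance_mm,
                "minute": m.minute,
                "t_min": m.t_min,
                "phase": m.phase,
                "path": f"measurements/{name}",
            }
        )
    manifest["measurements"] = records
    manifest["references"] = [
        {
            "parameter": param,
            "distance_mm": dist,
            "gain": ref["gain"],
            "path": f"references/{param}_{dist:g}mm",
        }
        for (param, dist), ref in dataset.references.items()
    ]
    manifest["snr_series"] = sorted(dataset.snr_series)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if dry_run:
        return out

    for m, rec in zip(dataset.measurements, records):
        mdir = out / rec["path"]
        mdir.mkdir(parents=True, exist_ok=True)
        _write_frames(mdir / "frames.tif", m.frames)
        tifffile.imwrite(mdir / "reference.tif", m.reference.values.astype(np.float32))
        tifffile.imwrite(mdir / "rr_truth.tif", m.rr_truth.astype(np.float32))
    for (param, dist), ref in dataset.references.items():
        rdir = out / "references" / f"{param}_{dist:g}mm"
        rdir.mkdir(parents=True, exist_ok=True)
        _write_frames(rdir / "white.tif", ref["white"])
        _write_frames(rdir / "dark.tif", ref["dark"])
    if dataset.snr_series:
        sdir = out / "snr"
        sdir.mkdir(exist_ok=True)
        for peak, stack in dataset.snr_series.items():
            tifffile.imwrite(sdir / f"band_{peak:g}nm.tif", stack)
    return out


def read_dataset(path: str | Path) -> StudyDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    root = Path(path)
    manifest = json.loads((root / "manifest.json").read_text())
    design = StudyDesign(
        measurements_per_participant=manifest["design"]["measurements_per_participant"],
        participants_per_distance=manifest["design"]["participants_per_distance"],
        distances_mm=tuple(manifest["design"]["distances_mm"]),
    )
    protocol = OcclusionProtocol(
        phases=tuple((label, dur) for label, dur in manifest["protocol"]["phases"]),
        frames_per_min=manifest["protocol"]["frames_per_min"],
        reference_blocks_per_min=manifest["protocol"]["reference_blocks_per_min"],
    )
    references = {}
    for rec in manifest["references"]:
        rdir = root / rec["path"]
        references[(rec["parameter"], rec["distance_mm"])] = {
            "white": _read_frames(rdir / "white.tif"),
            "dark": _read_frames(rdir / "dark.tif"),
            "gain": rec["gain"],
        }
    measurements = []
    for rec in manifest["measurements"]:
        mdir = root / rec["path"]
        frames = _read_frames(mdir / "frames.tif")
        ref_values = tifffile.imread(mdir / "reference.tif").astype(float)
        rr_truth = tifffile.imread(mdir / "rr_truth.tif").astype(float)
        measurements.append(
            Measurement(
                parameter=rec["parameter"],
                msi_parameter=rec["msi_parameter"],
                participant_id=rec["participant_id"],
                sex=rec["sex"],
                age=rec["age"],
                distance_mm=rec["distance_mm"],
                minute=rec["minute"],
                t_min=rec["t_min"],
                phase=rec["phase"],
                frames=frames,
                reference=ReferenceImage(
                    rec["parameter"], np.clip(ref_values, 0.0, 1.0), rec["minute"]
                ),
                rr_truth=rr_truth,
            )
        )
    snr_series = {}
    for peak in manifest.get("snr_series", []):
        snr_series[float(peak)] = tifffile.imread(root / "snr" / f"band_{peak:g}nm.tif")
    return StudyDataset(
        design=design,
        protocol=protocol,
        seed=manifest["seed"],
        shape=tuple(manifest["shape"]),
        parameters=tuple(manifest["parameters"]),
        reference_mode=manifest["reference_mode"],
        measurements=measurements,
        participants=manifest["participants"],
        references=references,
        snr_series=snr_series,
    )


def write_analysis(result, out_dir: str | Path) -> dict[str, Path]:
    """Write metrics, pair tables, MAE tables and test results of an analysis."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    metrics = result.metrics_frame()
    written["metrics_csv"] = out / "metrics.csv"
    metrics.to_csv(written["metrics_csv"], index=False)
    report = {"dropped_measurements": result.dropped_measurements, "parameters": {}}
    for param, pa in result.per_parameter.items():
        pdir = out / param
        pdir.mkdir(exist_ok=True)
        pa.pairs.to_csv(pdir / "marker_pairs.csv", index=False)
        pa.mae.to_csv(pdir / "mae.csv", index=False)
        report["parameters"][param] = {
            "msi_parameter": pa.msi_parameter,
            "model": {"slope": pa.model.slope, "intercept": pa.model.intercept},
            "n_pairs": len(pa.pairs),
            "n_calibration": len(pa.calibration_pairs),
            "n_test": len(pa.test_pairs),
            "mann_whitney": pa.mann_whitney,
        }
    written["report_json"] = out / "report.json"
    written["report_json"].write_text(json.dumps(report, indent=1))
    return written
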