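"""End-to-end quantitative pipeline over a synthetic occlusion study.

Chains acquisition (demultiplex + reflectance), perfusion (reflectance
ratios) and calibration (marker pairs, KS-balanced split, OLS fit, fivefold
cross-validation, test metrics, worst-case baseline, per-measurement MAE and
Mann--Whitney group comparisons) for each of the three parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import acquisition, calibration, perfusion
from .calibration import CircularMarker, EvalMetrics
from .phantom import Measurement, StudyDataset

__all__ = [
    "place_markers",
    "compute_rr_image",
    "build_marker_pairs",
    "AnalysisResult",
    "analyze_study",
    "metrics_table",
]


def place_markers(
    shape: tuple[int, int],
    n_markers: int = 8,
    radius: float = 3.0,
    rng: np.random.Generator | None = None,
    measurement_id: str = "",
) -> list[CircularMarker]:
    """Jittered-grid circular markers, all fully inside the image.

    Markers sit on a 2 x ceil(n/2) grid with seeded jitter of up to half a
    cell; the radius derives from the configured reference-object diameter.
    """
    if not (1 <= n_markers <= 8):
        raise ValueError("n_markers must lie in 1..8")
    if rng is None:
        rng = np.random.default_rng(0)
    rows, cols = 2, int(np.ceil(n_markers / 2))
    h, w = shape
    margin = radius + 1.0
    ys = np.linspace(margin, h - 1 - margin, rows)
    xs = np.linspace(margin, w - 1 - margin, cols)
    cell_y = (h - 2 * margin) / max(rows, 2) / 2.0
    cell_x = (w - 2 * margin) / max(cols, 2) / 2.0
    markers = []
    k = 0
    for y in ys:
        for x in xs:
            if k >= n_markers:
                break
            cy = float(np.clip(y + rng.uniform(-0.5, 0.5) * cell_y, margin, h - 1 - margin))
            cx = float(np.clip(x + rng.uniform(-0.5, 0.5) * cell_x, margin, w - 1 - margin))
            markers.append(
                CircularMarker(
                    center=(cy, cx),
                    radius=radius,
                    marker_id=k + 1,
                    measurement_id=measurement_id,
                )
            )
            k += 1
    return markers


def compute_rr_image(
    measurement: Measurement,
    dataset: StudyDataset,
    selections: Mapping[str, perfusion.BandSelection] | None = None,
    sequences: Mapping[str, acquisition.IlluminationSequence] | None = None,
) -> np.ma.MaskedArray:
    """Reflectance-ratio image of one measurement from its raw frames."""
    if selections is None:
        selections = perfusion.default_selections()
    if sequences is None:
        sequences = perfusion.default_sequences()
    seq = sequences[measurement.msi_parameter]
    refs = dataset.references[(measurement.parameter, measurement.distance_mm)]
    stack = acquisition.reflectance_stack(
        measurement.frames, refs["dark"], refs["white"], seq
    )
    return np.ma.asarray(
        perfusion.reflectance_ratio(stack, selections[measurement.msi_parameter])
    )


def _measurement_id(m: Measurement) -> str:
    return f"{m.parameter}_{m.distance_mm:g}mm_{m.participant_id}_b{m.minute:02d}"


def build_marker_pairs(
    dataset: StudyDataset,
    n_markers: int = 8,
    marker_radius: float = 3.0,
    seed: int = 0,
    selections: Mapping[str, perfusion.BandSelection] | None = None,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Marker-pair tables per parameter, plus the dropped-measurement log.

    Measurements whose marker disks contain saturated raw pixels (sensor
    override) are excluded and their ids returned in the log.
    """
    pairs: dict[str, list[dict]] = {p: [] for p in dataset.parameters}
    dropped: list[str] = []
    for mi, m in enumerate(dataset.measurements):
        mid = _measurement_id(m)
        rng = np.random.default_rng([seed, 7, mi])
        markers = place_markers(
            dataset.shape, n_markers, marker_radius, rng, measurement_id=mid
        )
        sat = np.zeros(dataset.shape, dtype=bool)
        for f in m.frames:
            sat |= np.any(f.pixels >= acquisition.FULL_SCALE, axis=-1)
        if any(sat[mk.mask(dataset.shape)].any() for mk in markers):
            dropped.append(mid)
            continue
        rr = compute_rr_image(m, dataset, selections)
        for mk in markers:
            pairs[m.parameter].append(
                {
                    "parameter": m.parameter,
                    "measurement_id": mid,
                    "marker_id": mk.marker_id,
                    "rr_mean": calibration.extract_marker_mean(rr, mk),
                    "p_ref": calibration.extract_marker_mean(m.reference.values, mk),
                    "distance_mm": m.distance_mm,
                    "participant_id": m.participant_id,
                    "sex": m.sex,
                    "age": m.age,
                }
            )
    tables = {p: pd.DataFrame(rows) for p, rows in pairs.items()}
    return tables, dropped


@dataclass
class ParameterAnalysis:
    """Per-parameter calibration outcome."""

    parameter: str
    msi_parameter: str
    pairs: pd.DataFrame
    calibration_pairs: pd.DataFrame
    test_pairs: pd.DataFrame
    model: perfusion.CalibrationModel
    cv_metrics: EvalMetrics
    test_metrics: EvalMetrics
    worst_case_metrics: EvalMetrics
    mae: pd.DataFrame
    mann_whitney: dict[str, dict]


@dataclass
class AnalysisResult:
    per_parameter: dict[str, ParameterAnalysis]
    dropped_measurements: list[str] = field(default_factory=list)

    def metrics_frame(self) -> pd.DataFrame:
        return metrics_table(self)


def _subset_metrics(model, test: pd.DataFrame) -> list[tuple[str, EvalMetrics]]:
    rows = []
    for dist in sorted(test["distance_mm"].unique()):
        sub = test[test["distance_mm"] == dist]
        if len(sub) >= 2:
            rows.append((f"test_{dist:g}mm", calibration.evaluate(model, sub)))
    for sex in ("male", "female"):
        sub = test[test["sex"] == sex]
        if len(sub) >= 2:
            rows.append((f"test_{sex}", calibration.evaluate(model, sub)))
    return rows


def analyze_study(
    dataset: StudyDataset,
    seed: int = 0,
    n_markers: int = 8,
    marker_radius: float = 3.0,
    calib_fraction: float = 0.7,
    n_candidates: int = 1000,
    cv_folds: int = 5,
    selections: Mapping[str, perfusion.BandSelection] | None = None,
) -> AnalysisResult:
    """Run the full quantitative pipeline on a synthetic study dataset."""
    tables, dropped = build_marker_pairs(
        dataset, n_markers, marker_radius, seed, selections
    )
    per_parameter: dict[str, ParameterAnalysis] = {}
    for param, pairs in tables.items():
        msi_param = perfusion.MSI_FOR_REFERENCE[param]
        cal, test = calibration.ks_split(
            pairs, calib_fraction=calib_fraction, n_candidates=n_candidates, seed=seed
        )
        model = calibration.fit_linear(cal, parameter=msi_param)
        cv = calibration.cross_validate(cal, k=cv_folds, seed=seed, parameter=msi_param)
        test_metrics = calibration.evaluate(model, test)
        worst = calibration.evaluate(calibration.worst_case_model(cal, msi_param), test)

        all_pairs = pairs.copy()
        all_pairs["p_msi"] = np.clip(model(all_pairs["rr_mean"].to_numpy()), 0.0, 1.0)
        mae = calibration.mae_aggregate(all_pairs)

        mw: dict[str, dict] = {}
        dists = sorted(mae["distance_mm"].unique())
        for a, b in [(x, y) for i, x in enumerate(dists) for y in dists[i + 1 :]]:
            ga = mae.loc[mae["distance_mm"] == a, "mae"]
            gb = mae.loc[mae["distance_mm"] == b, "mae"]
            if len(ga) and len(gb):
                u, p = calibration.mann_whitney_u(ga, gb)
                mw[f"distance_{a:g}_vs_{b:g}"] = {
                    "U": u, "p": p, "n_a": len(ga), "n_b": len(gb),
                }
        gm = mae.loc[mae["sex"] == "male", "mae"]
        gf = mae.loc[mae["sex"] == "female", "mae"]
        if len(gm) and len(gf):
            u, p = calibration.mann_whitney_u(gm, gf)
            mw["sex_male_vs_female"] = {"U": u, "p": p, "n_a": len(gm), "n_b": len(gf)}

        per_parameter[param] = ParameterAnalysis(
            parameter=param,
            msi_parameter=msi_param,
            pairs=pairs,
            calibration_pairs=cal,
            test_pairs=test,
            model=model,
            cv_metrics=cv,
            test_metrics=test_metrics,
            worst_case_metrics=worst,
            mae=mae,
            mann_whitney=mw,
        )
    return AnalysisResult(per_parameter=per_parameter, dropped_measurements=dropped)


def metrics_table(result: AnalysisResult) -> pd.DataFrame:
    """Long-format metrics table (parameter, subset, r2, rmse, rpd)."""
    rows = []
    for param, pa in result.per_parameter.items():
        subsets = [
            ("cv", pa.cv_metrics),
            ("test", pa.test_metrics),
            ("worst_case", pa.worst_case_metrics),
        ] + _subset_metrics(pa.model, pa.test_pairs)
        for name, m in subsets:
            rows.append(
                {
                    "parameter": pa.msi_parameter,
                    "subset": name,
                    "r2": m.r2,
                    "rmse": m.rmse,
                    "rpd": m.rpd,
                }
            )
    return pd.DataFrame(rows, columns=["parameter", "subset", "r2", "rmse", "rpd"])
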