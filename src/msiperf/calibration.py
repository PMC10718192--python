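"""Marker-based calibration of reflectance ratios against a reference device.

The quantitative pipeline: circular markers placed at anatomically
corresponding positions in each co-registered image pair yield (mean marker
RR, mean marker reference value) pairs; the pairs are split 70/30 with the
two-sample Kolmogorov--Smirnov distance between the reference-value
distributions minimised over seeded candidate splits; an ordinary
least-squares line P = m*RR + n is fitted per parameter on the calibration
set, evaluated by fivefold cross-validation and on the held-out test set with
RMSE, R^2 and the residual prediction deviation

    RPD = SD(reference values) / RMSE          (population SD)

and judged against a worst-case constant model (slope 0, intercept = mean
calibration reference value), for which RPD = 1 identically when the split
means match.  Per-measurement mean absolute errors feed Mann--Whitney U
tests for distance- and sex-dependence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CircularMarker",
    "MarkerPair",
    "EvalMetrics",
    "NoDataError",
    "DegenerateFitError",
    "extract_marker_mean",
    "ks_split",
    "fit_linear",
    "cross_validate",
    "evaluate",
    "worst_case_model",
    "mae_aggregate",
    "mann_whitney_u",
]

#: Columns of a marker-pair table.
PAIR_COLUMNS = (
    "parameter",
    "measurement_id",
    "marker_id",
    "rr_mean",
    "p_ref",
    "distance_mm",
    "participant_id",
    "sex",
    "age",
)


class NoDataError(ValueError):
    """A marker disk contains no valid (unmasked) pixels."""


class DegenerateFitError(ValueError):
    """The calibration abscissa has zero variance."""


@dataclass(frozen=True)
class CircularMarker:
    """A circular marker: center (row, col) in pixels, radius in pixels."""

    center: tuple[float, float]
    radius: float
    marker_id: int = 1
    measurement_id: str = ""

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if not (1 <= self.marker_id <= 8):
            raise ValueError("marker_id must lie in 1..8")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean disk mask: pixels whose centers lie within the radius
        (inclusive boundary)."""
        cy, cx = self.center
        if not (0 <= cy <= shape[0] - 1 and 0 <= cx <= shape[1] - 1):
            raise ValueError(f"marker center {self.center} outside image {shape}")
        if cy - self.radius < -0.5 or cy + self.radius > shape[0] - 0.5:
            raise ValueError("marker disk extends beyond image bounds")
        if cx - self.radius < -0.5 or cx + self.radius > shape[1] - 0.5:
            raise ValueError("marker disk extends beyond image bounds")
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= self.radius**2


@dataclass(frozen=True)
class MarkerPair:
    """One (mean marker RR, mean marker reference value) calibration pair."""

    rr_mean: float
    p_ref: float
    parameter: str
    measurement_id: str
    marker_id: int
    distance_mm: float = float("nan")
    participant_id: str = ""
    sex: str = ""
    age: int = -1

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_ref <= 1.0):
            raise ValueError("p_ref must lie in [0, 1]")
        if self.rr_mean <= 0:
            raise ValueError("rr_mean must be positive")


def pairs_to_frame(pairs: Iterable[MarkerPair]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(p, c) for c in PAIR_COLUMNS} for p in pairs])


def extract_marker_mean(image: np.ndarray, marker: CircularMarker) -> float:
    """Arithmetic mean over the pixels inside the marker disk.

    Masked pixels are excluded; a fully masked disk raises
    :class:`NoDataError`.
    """
    img = np.ma.asarray(image, dtype=float)
    disk = marker.mask(img.shape)
    vals = img[disk]
    if np.ma.count(vals) == 0:
        raise NoDataError(f"marker {marker.marker_id}: all pixels inside disk are masked")
    return float(np.ma.mean(vals))


# ---------------------------------------------------------------------------
# split / fit / evaluate
# ---------------------------------------------------------------------------


def ks_split(
    pairs: pd.DataFrame,
    calib_fraction: float = 0.7,
    n_candidates: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """KS-balanced random split into calibration and test sets.

    Evaluates ``n_candidates`` seeded random splits of size
    round(calib_fraction * N) and returns the one whose two-sample
    Kolmogorov--Smirnov statistic between the calibration and test reference
    values is minimal (first minimum on ties); deterministic given the seed.
    """
    if not (0.0 < calib_fraction < 1.0):
        raise ValueError("calib_fraction must lie strictly between 0 and 1")
    n = len(pairs)
    if n < 10:
        raise ValueError(f"need at least 10 pairs to split, got {n}")
    n_cal = int(np.floor(calib_fraction * n + 0.5))
    if n_cal in (0, n):
        raise ValueError("split would leave one side empty")
    rng = np.random.default_rng(seed)
    p_ref = pairs["p_ref"].to_numpy()
    best_stat = np.inf
    best_idx: np.ndarray | None = None
    for _ in range(n_candidates):
        perm = rng.permutation(n)
        cal_idx = perm[:n_cal]
        test_idx = perm[n_cal:]
        stat = stats.ks_2samp(p_ref[cal_idx], p_ref[test_idx]).statistic
        if stat < best_stat:
            best_stat = stat
            best_idx = perm
    assert best_idx is not None
    cal = pairs.iloc[np.sort(best_idx[:n_cal])].reset_index(drop=True)
    test = pairs.iloc[np.sort(best_idx[n_cal:])].reset_index(drop=True)
    return cal, test


def fit_linear(pairs: pd.DataFrame, parameter: str | None = None):
    """Ordinary least-squares line of p_ref on rr_mean (closed form)."""
    from .perfusion import CalibrationModel

    rr = pairs["rr_mean"].to_numpy(dtype=float)
    p = pairs["p_ref"].to_numpy(dtype=float)
    if np.unique(rr).size < 2:
        raise DegenerateFitError("rr_mean has zero variance; cannot fit a line")
    rr_c = rr - rr.mean()
    slope = float(np.dot(rr_c, p - p.mean()) / np.dot(rr_c, rr_c))
    intercept = float(p.mean() - slope * rr.mean())
    if parameter is None:
        parameter = str(pairs["parameter"].iloc[0]) if "parameter" in pairs else "i.tHb"
    return CalibrationModel(parameter=parameter, slope=slope, intercept=intercept)


@dataclass(frozen=True)
class EvalMetrics:
    """RMSE, coefficient of determination and residual prediction deviation."""

    rmse: float
    r2: float
    rpd: float
    n: int = 0

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")
        if self.rpd < 0:
            raise ValueError("rpd must be non-negative")


def evaluate(model, pairs: pd.DataFrame) -> EvalMetrics:
    """Evaluate a calibration model on held-out pairs.

    Predictions are un-clipped; R^2 = 1 - SS_res/SS_tot on the held-out
    references (may be negative); RPD uses the population SD so a constant
    predictor at the evaluated set's mean gives RPD = 1 exactly.  RMSE = 0 is
    reported with an infinite RPD.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to evaluate")
    rr = pairs["rr_mean"].to_numpy(dtype=float)
    p = pairs["p_ref"].to_numpy(dtype=float)
    pred = model(rr)
    resid = pred - p
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    sd = float(np.std(p))  # population SD
    rpd = np.inf if rmse == 0 else sd / rmse
    return EvalMetrics(rmse=rmse, r2=r2, rpd=rpd, n=len(pairs))


def cross_validate(
    pairs: pd.DataFrame, k: int = 5, seed: int = 0, parameter: str | None = None
) -> EvalMetrics:
    """Seeded shuffled k-fold cross-validation; metrics averaged over folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(pairs)
    if n < k:
        raise ValueError(f"need at least k={k} pairs, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    rmses, r2s, rpds = [], [], []
    for i in range(k):
        test_idx = folds[i]
        train_idx = np.concatenate([folds[j] for j in range(k) if j != i])
        model = fit_linear(pairs.iloc[train_idx], parameter=parameter)
        m = evaluate(model, pairs.iloc[test_idx]) if len(test_idx) >= 2 else None
        if m is None:
            # leave-one-out fold: RMSE is the absolute residual; R^2/RPD undefined
            row = pairs.iloc[test_idx]
            resid = float(model(row["rr_mean"].to_numpy())[0] - row["p_ref"].to_numpy()[0])
            rmses.append(abs(resid))
            continue
        rmses.append(m.rmse)
        r2s.append(m.r2)
        rpds.append(m.rpd)
    return EvalMetrics(
        rmse=float(np.mean(rmses)),
        r2=float(np.mean(r2s)) if r2s else 0.0,
        rpd=float(np.mean(rpds)) if rpds else 0.0,
        n=n,
    )


def worst_case_model(pairs: pd.DataFrame, parameter: str | None = None):
    """Constant predictor at the calibration set's mean reference value."""
    from .perfusion import CalibrationModel

    if len(pairs) < 1:
        raise ValueError("need at least 1 pair")
    if parameter is None:
        parameter = str(pairs["parameter"].iloc[0]) if "parameter" in pairs else "i.tHb"
    return CalibrationModel(
        parameter=parameter, slope=0.0, intercept=float(pairs["p_ref"].mean())
    )


# ---------------------------------------------------------------------------
# per-measurement aggregation and group comparison
# ---------------------------------------------------------------------------


def mae_aggregate(pairs: pd.DataFrame, prediction_column: str = "p_msi") -> pd.DataFrame:
    """Per-measurement mean absolute error over that measurement's markers.

    The markers of one measurement are statistically dependent, so their
    differences are collapsed into one MAE per measurement before any group
    test; the default design yields 16 independent MAE values per participant.
    """
    if len(pairs) == 0:
        raise ValueError("pairs table is empty")
    df = pairs.copy()
    df["abs_err"] = (df[prediction_column] - df["p_ref"]).abs()
    keys = [c for c in ("parameter", "participant_id", "distance_mm", "sex", "measurement_id") if c in df]
    out = df.groupby(keys, as_index=False, sort=True)["abs_err"].mean()
    return out.rename(columns={"abs_err": "mae"})


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Rank-sum U of group a with midrank tie handling."""
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    ra = ranks[: a.size].sum()
    return float(ra - a.size * (a.size + 1) / 2.0)


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float], exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Mann--Whitney U test.

    Returns (U of group a, two-sided p).  For groups of at most
    ``exact_max_n`` each, the null distribution of U is enumerated exactly
    over all label assignments (valid under ties); larger groups use the
    tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_a = _u_statistic(a, b)
    if a.size <= exact_max_n and b.size <= exact_max_n:
        combined = np.concatenate([a, b])
        n = combined.size
        mid = a.size * b.size / 2.0
        obs_dev = abs(u_a - mid)
        count = 0
        total = 0
        for idx in combinations(range(n), a.size):
            idx = np.array(idx)
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            u = _u_statistic(combined[mask], combined[~mask])
            total += 1
            # two-sided: as or more extreme in |U - n_a n_b / 2|
            if abs(u - mid) >= obs_dev - 1e-12:
                count += 1
        p = count / total
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return u_a, min(1.0, float(p))
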