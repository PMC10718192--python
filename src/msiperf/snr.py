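"""Frame-deviation signal-to-noise metric, scalar and spatially resolved.

The SNR of a band is computed from N repeated acquisitions of a static
target as the average decibel ratio of the mean signal to each frame's
deviation from it:

    SNR = (1/N) * sum_i 20 * log10( v_bar / |v_i - v_bar| )

with v_i the mean pixel value of frame i and v_bar the mean over all frames.
The metric is scale-invariant and, for additive Gaussian noise of width
sigma << v_bar, sits a fixed ~5.52 dB above 20*log10(v_bar/sigma) (the
expectation of -20*log10|Z| for standard normal Z).  Terms with |v_i - v_bar|
below a full-scale-relative epsilon are undefined and excluded (counted).

The spatially resolved variant applies the same formula per pixel over the
frame axis and reports mean horizontal/vertical line profiles of the map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .acquisition import FULL_SCALE
from .spectral import SpectralBand

__all__ = [
    "SNRResult",
    "DegenerateSignalError",
    "snr_scalar",
    "snr_map",
    "snr_for_band",
    "write_snr_report",
]

#: Deviations below this fraction of full scale count as degenerate terms.
EPSILON_FRACTION = 1e-6


class DegenerateSignalError(ValueError):
    """All frames are identical: every term of the SNR sum is undefined."""


@dataclass
class SNRResult:
    """Per-band SNR: scalar dB, optional per-pixel map and line profiles."""

    band: SpectralBand | None
    snr_db: float
    n_frames: int
    excluded_terms: int = 0
    map_db: np.ndarray | None = None
    profile_horizontal: np.ndarray | None = None
    profile_vertical: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.excluded_terms >= self.n_frames:
            raise ValueError("excluded_terms must be < n_frames")


def _snr_terms(values: np.ndarray, full_scale: float) -> tuple[float, int]:
    mean = values.mean()
    dev = np.abs(values - mean)
    eps = EPSILON_FRACTION * full_scale
    ok = dev >= eps
    n_ok = int(np.count_nonzero(ok))
    if n_ok == 0:
        raise DegenerateSignalError("all frame values identical; SNR is infinite")
    snr = float(np.mean(20.0 * np.log10(mean / dev[ok])))
    return snr, values.size - n_ok


def snr_scalar(frame_means: Sequence[float], full_scale: float = FULL_SCALE) -> float:
    """Scalar SNR in dB from per-frame mean pixel values."""
    values = np.asarray(frame_means, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 frames")
    snr, _ = _snr_terms(values, full_scale)
    return snr


def snr_scalar_detail(
    frame_means: Sequence[float], full_scale: float = FULL_SCALE
) -> tuple[float, int]:
    """As :func:`snr_scalar` but also returns the excluded-term count."""
    values = np.asarray(frame_means, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 frames")
    return _snr_terms(values, full_scale)


def snr_map(
    frames: np.ndarray, full_scale: float = FULL_SCALE
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel SNR map plus mean horizontal and vertical line profiles.

    ``frames`` is an (N, H, W) stack.  Returns ``(map_db, horizontal,
    vertical)`` where the horizontal profile (length W) is the column-wise
    mean of the map and the vertical profile (length H) the row-wise mean.
    Pixels whose deviations are all degenerate yield NaN.
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("frames must be an (N>=2, H, W) stack")
    mean = stack.mean(axis=0)
    dev = np.abs(stack - mean)
    eps = EPSILON_FRACTION * full_scale
    ok = dev >= eps
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(ok, 20.0 * np.log10(mean[None] / np.where(ok, dev, 1.0)), np.nan)
    n_ok = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        map_db = np.nansum(terms, axis=0) / n_ok
    map_db[n_ok == 0] = np.nan
    horizontal = np.nanmean(map_db, axis=0)
    vertical = np.nanmean(map_db, axis=1)
    return map_db, horizontal, vertical


def snr_for_band(
    frames: np.ndarray,
    band: SpectralBand | None = None,
    full_scale: float = FULL_SCALE,
    with_map: bool = True,
) -> SNRResult:
    """Full SNR evaluation of an (N, H, W) frame stack for one band.

    The scalar uses per-frame spatial means (the map's pixel-mean variant is
    available from the returned map).
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("frames must be an (N>=2, H, W) stack")
    frame_means = stack.mean(axis=(1, 2))
    snr, excluded = _snr_terms(frame_means, full_scale)
    result = SNRResult(
        band=band, snr_db=snr, n_frames=stack.shape[0], excluded_terms=excluded
    )
    if with_map:
        result.map_db, result.profile_horizontal, result.profile_vertical = snr_map(
            stack, full_scale
        )
    return result


def write_snr_report(result: SNRResult, out_dir: str | Path, stem: str = "snr") -> dict:
    """Write scalar + profiles as CSV and the map as 32-bit float TIFF."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    scalar = pd.DataFrame(
        [
            {
                "band_peak_nm": result.band.peak_nm if result.band else np.nan,
                "snr_db": result.snr_db,
                "n_frames": result.n_frames,
                "excluded_terms": result.excluded_terms,
            }
        ]
    )
    scalar_path = out_dir / f"{stem}_scalar.csv"
    scalar.to_csv(scalar_path, index=False)
    written["scalar"] = scalar_path
    if result.map_db is not None:
        map_path = out_dir / f"{stem}_map.tif"
        tifffile.imwrite(map_path, result.map_db.astype(np.float32))
        written["map"] = map_path
        prof = pd.DataFrame(
            {
                "index": np.arange(
                    max(result.profile_horizontal.size, result.profile_vertical.size)
                )
            }
        )
        prof["horizontal_db"] = pd.Series(result.profile_horizontal)
        prof["vertical_db"] = pd.Series(result.profile_vertical)
        prof_path = out_dir / f"{stem}_profiles.csv"
        prof.to_csv(prof_path, index=False)
        written["profiles"] = prof_path
    return written
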