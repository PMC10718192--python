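"""Spectral system model: emitters, sensor filters, and effective bands.

The imaging system switches 14 narrow-band LEDs (nominal 405--960 nm) in front
of a colour CMOS sensor.  What the camera actually measures in one colour
channel is not the LED's nominal line but the *effective band*: the product of
the LED emission spectrum, the sensor's R/G/B filter curve and the transmission
of the light guide and optics.  Broad emitters can overlap two filter curves,
which is why 14 LEDs yield 16 usable effective wavelengths.

This module provides

* :class:`SpectralCurve` / :class:`SpectralBand` -- the curve and band types,
* :func:`gaussian_emitter` -- parametric stand-in for unpublished LED spectra,
* :func:`effective_spectrum` -- the generic emitter x filter x transmission
  band-derivation engine,
* :func:`canonical_bands` -- the authoritative 16-entry band table of the
  system (peak wavelength and FWHM per band).

The vendor's measured LED and filter curves are not public; the canonical band
table is therefore hard-coded, and the engine is exercised on parametric
fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GRID_NM",
    "CHANNELS",
    "SpectralCurve",
    "SpectralBand",
    "gaussian_emitter",
    "curve_fwhm",
    "effective_spectrum",
    "canonical_bands",
    "band_by_peak",
    "write_band_table",
    "read_band_table",
]

#: Common wavelength grid of the system: 1 nm spacing over the sensor range.
GRID_NM = np.arange(400.0, 1001.0, 1.0)

#: Sensor colour channels, in raster (array-axis) order.
CHANNELS = ("R", "G", "B")

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SpectralCurve:
    """A sampled relative spectrum (emission, filter or transmission).

    ``values`` are dimensionless relative intensities/transmissions on a
    strictly increasing wavelength grid in nm.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        va = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.shape != va.shape:
            raise ValueError("wavelengths and values must be 1-D arrays of equal length")
        if wl.size < 2:
            raise ValueError("a spectral curve needs at least two samples")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(va < 0):
            raise ValueError("spectral values must be non-negative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", va)

    def resample(self, grid: np.ndarray) -> "SpectralCurve":
        """Linearly interpolate onto ``grid``; zero outside the support."""
        grid = np.asarray(grid, dtype=float)
        vals = np.interp(grid, self.wavelengths_nm, self.values, left=0.0, right=0.0)
        return SpectralCurve(grid, vals)


@dataclass(frozen=True)
class SpectralBand:
    """One effective spectral band of the system.

    ``emitter_id`` names the LED producing the band and ``channel`` the sensor
    colour channel through which it is read out.
    """

    peak_nm: float
    fwhm_nm: float
    emitter_id: str
    channel: str

    def __post_init__(self) -> None:
        if not (400.0 <= self.peak_nm <= 1000.0):
            raise ValueError(f"band peak {self.peak_nm} nm outside the 400-1000 nm system range")
        if self.fwhm_nm <= 0:
            raise ValueError("FWHM must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")

    @property
    def depth_class(self) -> str:
        """Penetration-depth class: green/blue light stays superficial,
        red/NIR light probes deeper layers."""
        return "sup" if self.peak_nm < DEPTH_SPLIT_NM else "deep"


#: Wavelength separating superficial from deep sensing bands (repo decision).
DEPTH_SPLIT_NM = 620.0


def gaussian_emitter(peak_nm: float, fwhm_nm: float, grid: np.ndarray | None = None) -> SpectralCurve:
    """Unit-peak Gaussian emission curve, parameterised by peak and FWHM.

    Stand-in for an unpublished LED emission spectrum.
    """
    if grid is None:
        grid = GRID_NM
    grid = np.asarray(grid, dtype=float)
    if fwhm_nm <= 0:
        raise ValueError("fwhm_nm must be positive")
    if not (grid[0] <= peak_nm <= grid[-1]):
        raise ValueError(f"peak {peak_nm} nm outside grid range [{grid[0]}, {grid[-1]}] nm")
    sigma = fwhm_nm * _FWHM_TO_SIGMA
    vals = np.exp(-0.5 * ((grid - peak_nm) / sigma) ** 2)
    return SpectralCurve(grid, vals)


def curve_fwhm(curve: SpectralCurve) -> float:
    """Full width at half maximum by linear interpolation of the half-maximum
    crossings around the global peak.

    If the curve never drops below half maximum on one side, the grid edge is
    used for that side (width truncated by the sampling window).
    """
    wl, va = curve.wavelengths_nm, curve.values
    i_pk = int(np.argmax(va))
    half = va[i_pk] / 2.0
    if va[i_pk] <= 0:
        raise ValueError("curve is identically zero; FWHM undefined")

    # walk left from the peak to the last sample still >= half
    left = wl[0]
    for i in range(i_pk, 0, -1):
        if va[i - 1] < half:
            # crossing between i-1 and i
            f = (half - va[i - 1]) / (va[i] - va[i - 1])
            left = wl[i - 1] + f * (wl[i] - wl[i - 1])
            break
    right = wl[-1]
    for i in range(i_pk, len(wl) - 1):
        if va[i + 1] < half:
            f = (half - va[i + 1]) / (va[i] - va[i + 1])
            right = wl[i + 1] - f * (wl[i + 1] - wl[i])
            break
    return float(right - left)


def effective_spectrum(
    emitters: Mapping[str, SpectralCurve],
    sensor_filters: Mapping[str, SpectralCurve],
    transmission: SpectralCurve,
    peak_threshold: float = 0.05,
    grid: np.ndarray | None = None,
) -> list[SpectralBand]:
    """Derive effective bands from emitter x filter x transmission products.

    For every (emitter, channel) pair the product curve is formed on a common
    grid.  An emitter contributes one band per channel whose product maximum
    exceeds ``peak_threshold`` times that emitter's strongest product across
    all channels; the band peak is the argmax and the width the interpolated
    FWHM of the product.  The threshold decides which filter overlaps count as
    usable bands (the instrument's own criterion is not public; 5% is this
    package's default).
    """
    if not emitters:
        raise ValueError("emitters must not be empty")
    if not (0.0 < peak_threshold < 1.0):
        raise ValueError("peak_threshold must lie strictly between 0 and 1")
    missing = set(CHANNELS) - set(sensor_filters)
    if missing:
        raise ValueError(f"sensor_filters missing channels: {sorted(missing)}")
    if grid is None:
        grid = GRID_NM
    grid = np.asarray(grid, dtype=float)

    trans = transmission.resample(grid).values
    filt = {ch: sensor_filters[ch].resample(grid).values for ch in CHANNELS}

    bands: list[SpectralBand] = []
    for emitter_id, emitter in emitters.items():
        em = emitter.resample(grid).values
        products = {ch: em * filt[ch] * trans for ch in CHANNELS}
        global_max = max(float(p.max()) for p in products.values())
        if global_max <= 0:
            continue
        for ch, prod in products.items():
            if float(prod.max()) > peak_threshold * global_max:
                prod_curve = SpectralCurve(grid, prod)
                # center of the maximal plateau (flat-topped products)
                at_max = np.flatnonzero(prod >= prod.max() * (1.0 - 1e-12))
                peak = float(grid[at_max].mean())
                bands.append(
                    SpectralBand(
                        peak_nm=peak,
                        fwhm_nm=curve_fwhm(prod_curve),
                        emitter_id=emitter_id,
                        channel=ch,
                    )
                )
    bands.sort(key=lambda b: b.peak_nm)
    return bands


# The system's 16 effective bands: peak / FWHM in nm as measured for the
# instrument, with this package's emitter and readout-channel assignment.
# Two emitters contribute two bands each (broad emission overlapping two
# filter curves); the 863 nm band is read through the blue channel, where the
# NIR leakage of the dye filter is strong enough, so that it can share a slot
# with another red-channel NIR band.
_CANONICAL_TABLE: tuple[tuple[float, float, str, str], ...] = (
    (404.0, 12.0, "L404", "B"),
    (426.0, 16.0, "L426", "B"),
    (450.0, 21.0, "L460", "B"),
    (503.0, 32.0, "L460", "G"),
    (519.0, 38.0, "L519", "G"),
    (532.0, 75.0, "L532", "G"),
    (537.0, 75.0, "L537", "G"),
    (580.0, 57.0, "L585", "G"),
    (590.0, 84.0, "L585", "R"),
    (600.0, 49.0, "L600", "R"),
    (635.0, 17.0, "L635", "R"),
    (663.0, 20.0, "L663", "R"),
    (762.0, 32.0, "L762", "R"),
    (811.0, 36.0, "L811", "R"),
    (863.0, 49.0, "L863", "B"),
    (957.0, 43.0, "L957", "R"),
)


def canonical_bands() -> list[SpectralBand]:
    """The authoritative 16-entry effective band table, sorted by peak."""
    return [SpectralBand(p, f, e, c) for p, f, e, c in _CANONICAL_TABLE]


def band_by_peak(peak_nm: float, bands: Iterable[SpectralBand] | None = None) -> SpectralBand:
    """Look up a band by its peak wavelength (exact match)."""
    for band in bands if bands is not None else canonical_bands():
        if band.peak_nm == peak_nm:
            return band
    raise KeyError(f"no band with peak {peak_nm} nm")


def write_band_table(bands: Iterable[SpectralBand], path: str | Path) -> None:
    """Write a band table as CSV (emitter_id, channel, peak_nm, fwhm_nm)."""
    df = pd.DataFrame(
        [
            {
                "emitter_id": b.emitter_id,
                "channel": b.channel,
                "peak_nm": repr(b.peak_nm),
                "fwhm_nm": repr(b.fwhm_nm),
            }
            for b in bands
        ]
    )
    df.to_csv(path, index=False)


def read_band_table(path: str | Path) -> list[SpectralBand]:
    """Read a band table written by :func:`write_band_table` (bit-exact)."""
    df = pd.read_csv(path, dtype={"emitter_id": str, "channel": str})
    return [
        SpectralBand(
            peak_nm=float(row.peak_nm),
            fwhm_nm=float(row.fwhm_nm),
            emitter_id=row.emitter_id,
            channel=row.channel,
        )
        for row in df.itertuples()
    ]


def write_curve(curve: SpectralCurve, path: str | Path) -> None:
    """Write a spectral curve as two-column CSV (wavelength_nm, value)."""
    pd.DataFrame({"wavelength_nm": curve.wavelengths_nm, "value": curve.values}).to_csv(
        path, index=False
    )


def read_curve(path: str | Path) -> SpectralCurve:
    df = pd.read_csv(path)
    return SpectralCurve(df["wavelength_nm"].to_numpy(), df["value"].to_numpy())
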