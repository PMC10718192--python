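"""Reflectance-ratio perfusion parameters and calibrated parameter maps.

Like the ratio-of-ratios principle of pulse oximetry, each tissue parameter
is derived from the ratio of mean reflectances in two spectral ranges with
opposing HbO2/HHb absorption:

    RR = mean_{s1} R(lambda) / mean_{s2} R(lambda)

* i.tHb (hemoglobin content): strongly absorbed green bands over a band near
  the 800 nm isosbestic point, where absorption is saturation-insensitive.
* i.StO2 (deep oxygenation): a red band (HHb >> HbO2) over NIR bands; RR
  grows with oxygenation.
* i.StO2sup (superficial oxygenation): green bands (small penetration depth)
  over an NIR band.

A per-parameter affine calibration P = m * RR + n, fitted against a clinical
reference device, maps the raw ratio onto the reference's [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .acquisition import IlluminationSequence, Slot
from .spectral import SpectralBand, canonical_bands

__all__ = [
    "MSI_PARAMETERS",
    "REFERENCE_FOR_MSI",
    "MSI_FOR_REFERENCE",
    "BandSelection",
    "CalibrationModel",
    "ParameterImage",
    "default_selections",
    "default_sequences",
    "reflectance_ratio",
    "parameter_image",
    "render_timelapse",
]

#: The three MSI perfusion parameters and the reference parameter each is
#: calibrated against.
MSI_PARAMETERS = ("i.tHb", "i.StO2", "i.StO2sup")
REFERENCE_FOR_MSI = {"i.tHb": "THI", "i.StO2": "NIR_PI", "i.StO2sup": "StO2"}
MSI_FOR_REFERENCE = {v: k for k, v in REFERENCE_FOR_MSI.items()}


@dataclass(frozen=True)
class BandSelection:
    """Numerator (s1) and denominator (s2) band peaks for one parameter."""

    parameter: str
    s1_bands: tuple[float, ...]
    s2_bands: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.parameter not in MSI_PARAMETERS:
            raise ValueError(f"parameter must be one of {MSI_PARAMETERS}")
        s1, s2 = tuple(self.s1_bands), tuple(self.s2_bands)
        if not s1 or not s2:
            raise ValueError("s1 and s2 must be non-empty")
        if set(s1) & set(s2):
            raise ValueError("s1 and s2 must be disjoint")
        peaks = {b.peak_nm for b in canonical_bands()}
        unknown = (set(s1) | set(s2)) - peaks
        if unknown:
            raise ValueError(f"peaks {sorted(unknown)} nm not in the canonical band table")
        object.__setattr__(self, "s1_bands", s1)
        object.__setattr__(self, "s2_bands", s2)


@dataclass(frozen=True)
class CalibrationModel:
    """Affine calibration P = slope * RR + intercept for one parameter."""

    parameter: str
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("calibration coefficients must be finite")

    def __call__(self, rr: np.ndarray) -> np.ndarray:
        return self.slope * rr + self.intercept


@dataclass(frozen=True)
class ParameterImage:
    """A calibrated parameter map in [0, 1] (masked pixels stay masked)."""

    parameter: str
    values: np.ndarray
    source: str = "MSI"

    def __post_init__(self) -> None:
        if self.source not in ("MSI", "reference"):
            raise ValueError("source must be 'MSI' or 'reference'")
        vals = self.values
        if np.ma.isMaskedArray(vals):
            comp = vals.compressed()
        else:
            comp = np.asarray(vals, dtype=float).ravel()
        if comp.size and (comp.min() < 0 or comp.max() > 1):
            raise ValueError("parameter values must be clipped to [0, 1]")


def default_selections() -> dict[str, BandSelection]:
    """The package's default band selections per parameter.

    i.tHb relates the strongly absorbed 532/537 nm green bands to the 811 nm
    band next to the isosbestic point; i.StO2 relates 663 nm to 811/863 nm;
    i.StO2sup relates the green bands to 863 nm.  All selections are
    configurable; the 450 nm blue band is acquired for the colour image only
    and excluded from the hemoglobin ratio by default.
    """
    return {
        "i.tHb": BandSelection("i.tHb", (532.0, 537.0), (811.0,)),
        "i.StO2": BandSelection("i.StO2", (663.0,), (811.0, 863.0)),
        "i.StO2sup": BandSelection("i.StO2sup", (532.0, 537.0), (863.0,)),
    }


def default_sequences() -> dict[str, IlluminationSequence]:
    """Default 3-slot illumination sequences per parameter.

    Two slots carry the parameter bands (channel-disjoint within each slot),
    the third an RGB colour image (one blue, one green, one red emitter).
    """
    rgb = Slot(["L404", "L519", "L635"])
    return {
        "i.tHb": IlluminationSequence([Slot(["L532", "L811"]), Slot(["L537"]), rgb]),
        "i.StO2": IlluminationSequence([Slot(["L663"]), Slot(["L811", "L863"]), rgb]),
        "i.StO2sup": IlluminationSequence([Slot(["L532", "L863"]), Slot(["L537"]), rgb]),
    }


def reflectance_ratio(
    stack: Mapping[float, np.ndarray],
    selection: BandSelection,
    postprocess=None,
) -> np.ndarray:
    """Reflectance-ratio image for one parameter.

    ``stack`` maps band peak (nm) to a reflectance image (plain or masked).
    The ratio is the unweighted mean over the s1 bands divided by the
    unweighted mean over the s2 bands; pixels with non-positive denominator
    are masked.  ``postprocess`` is an optional per-range reflectance hook
    (the identity by default; the clinical reference device applies an
    undisclosed smoothing here).
    """
    if hasattr(stack, "as_dict"):
        stack = stack.as_dict()
    missing = (set(selection.s1_bands) | set(selection.s2_bands)) - set(stack)
    if missing:
        raise ValueError(f"stack is missing bands {sorted(missing)} nm")
    if postprocess is None:
        postprocess = lambda x: x  # noqa: E731

    def _range_mean(peaks: Sequence[float]):
        imgs = [np.ma.asarray(postprocess(stack[p]), dtype=float) for p in peaks]
        return np.ma.mean(np.ma.stack(imgs), axis=0)

    num = _range_mean(selection.s1_bands)
    den = _range_mean(selection.s2_bands)
    den = np.ma.masked_less_equal(den, 0.0)
    rr = num / den
    if not np.ma.is_masked(rr):
        return np.asarray(rr)
    return rr


def parameter_image(rr: np.ndarray, model: CalibrationModel, clip: bool = True):
    """Apply the affine calibration to an RR image.

    With ``clip`` (the default) the result is a :class:`ParameterImage`
    clipped to [0, 1]; with ``clip=False`` the raw affine image is returned
    as an array (out-of-range values allowed, e.g. for linearity checks).
    """
    p = model(np.ma.asarray(rr, dtype=float))
    if not clip:
        return p if np.ma.is_masked(p) else np.asarray(p)
    p = np.ma.clip(p, 0.0, 1.0)
    if not np.ma.is_masked(p):
        p = np.asarray(p)
    return ParameterImage(parameter=model.parameter, values=p, source="MSI")


def render_timelapse(
    parameter_images: Sequence[ParameterImage],
    reference_images: Sequence,
    out_dir: str | Path,
    cmap: str = "viridis",
) -> list[Path]:
    """Write side-by-side false-colour comparison frames (one PNG per block).

    Both panels use the same colormap with a fixed [0, 1] scale; masked MSI
    pixels are rendered black.
    """
    import imageio.v3 as iio
    from matplotlib import colormaps

    if len(parameter_images) != len(reference_images):
        raise ValueError("need one reference image per parameter image")
    cm = colormaps[cmap]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, (pim, ref) in enumerate(zip(parameter_images, reference_images)):
        left = np.ma.filled(np.ma.asarray(pim.values, dtype=float), np.nan)
        right = np.asarray(getattr(ref, "values", ref), dtype=float)
        if left.shape != right.shape:
            raise ValueError("parameter and reference images must share one shape")
        panel = np.concatenate([left, right], axis=1)
        rgba = cm(np.clip(np.nan_to_num(panel, nan=0.0), 0.0, 1.0))
        rgba[np.isnan(panel)] = (0.0, 0.0, 0.0, 1.0)
        frame = (rgba[:, :, :3] * 255).astype(np.uint8)
        path = out_dir / f"frame_{i:03d}.png"
        iio.imwrite(path, frame)
        paths.append(path)
    return paths
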