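"""Illumination sequences, raw-frame rendering, demultiplexing, reflectance.

A *sequence* describes which LEDs light up during the exposure of up to three
RGB images captured in a loop; an image carries the *image index* 1, 2 or 3.
Spectral separation of simultaneously lit LEDs relies on them feeding
different colour channels of the sensor; LEDs that would share a channel must
go into different slots.  After demultiplexing, per-band intensity images are
converted to reflectance with dark and white reference images:

    R = (I_raw - I_D) / (I_W - I_D)

Pixels where the white reference does not exceed the dark reference are
masked and propagate as invalid downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .spectral import CHANNELS, SpectralBand, canonical_bands

__all__ = [
    "FULL_SCALE",
    "DARK_LEVEL_DN",
    "Slot",
    "IlluminationSequence",
    "RawFrame",
    "ReflectanceStack",
    "DemuxInfeasibleError",
    "IncompleteSequenceError",
    "sequence_bands",
    "check_demultiplexable",
    "auto_gain",
    "noise_sigma_for_target",
    "render_raw",
    "demultiplex",
    "reflectance",
    "switching_check",
]

#: 10-bit sensor full scale.
FULL_SCALE = 1023

#: Constant sensor background level in DN (measured dark signal of the
#: instrument class this simulates; small but modelled for reflectance
#: fidelity).
DARK_LEVEL_DN = 1.3

#: An emitter counts as "mapping to" a channel when its band weight there
#: exceeds this fraction of its strongest channel weight.
CROSSTALK_THRESHOLD = 0.05

_CH_INDEX = {ch: i for i, ch in enumerate(CHANNELS)}


class DemuxInfeasibleError(ValueError):
    """Two emitters in one slot feed the same colour channel."""


class IncompleteSequenceError(ValueError):
    """A sequence pass is missing one or more image indexes."""


@dataclass(frozen=True)
class Slot:
    """One image slot: the set of (emitter_id, on_time fraction) active during
    that exposure."""

    emitters: tuple[tuple[str, float], ...]

    def __init__(self, emitters: Iterable[tuple[str, float] | str]):
        norm = []
        for e in emitters:
            if isinstance(e, str):
                norm.append((e, 1.0))
            else:
                eid, on = e
                if not (0.0 < on <= 1.0):
                    raise ValueError("on_time fraction must lie in (0, 1]")
                norm.append((str(eid), float(on)))
        object.__setattr__(self, "emitters", tuple(norm))

    @property
    def emitter_ids(self) -> tuple[str, ...]:
        return tuple(e for e, _ in self.emitters)


@dataclass(frozen=True)
class IlluminationSequence:
    """An ordered list of 1-3 slots, optionally looped by the sensor."""

    slots: tuple[Slot, ...]
    loop: bool = True

    def __init__(self, slots: Sequence[Slot], loop: bool = True):
        slots = tuple(slots)
        if not (1 <= len(slots) <= 3):
            raise ValueError("a sequence has between 1 and 3 slots")
        object.__setattr__(self, "slots", slots)
        object.__setattr__(self, "loop", bool(loop))

    def __len__(self) -> int:
        return len(self.slots)


@dataclass(frozen=True)
class RawFrame:
    """One 10-bit RGB image (H x W x 3, DN in [0, 1023])."""

    pixels: np.ndarray
    image_index: int
    frame_number: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if px.min() < 0 or px.max() > FULL_SCALE:
            raise ValueError(f"pixel values must lie in [0, {FULL_SCALE}]")
        if self.image_index not in (1, 2, 3):
            raise ValueError("image_index must be 1, 2 or 3")
        object.__setattr__(self, "pixels", px)

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[:, :, _CH_INDEX[name]].astype(float)


@dataclass
class ReflectanceStack:
    """Per-band reflectance images (masked arrays; invalid pixels masked)."""

    bands: list[SpectralBand]
    images: list[np.ma.MaskedArray]

    def __post_init__(self) -> None:
        if len(self.bands) != len(self.images):
            raise ValueError("one image per band required")
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError("all reflectance images must share one shape")

    def as_dict(self) -> dict[float, np.ma.MaskedArray]:
        return {b.peak_nm: im for b, im in zip(self.bands, self.images)}


# ---------------------------------------------------------------------------
# sequence geometry
# ---------------------------------------------------------------------------


def _bands_by_emitter(bands: Sequence[SpectralBand]) -> dict[str, list[SpectralBand]]:
    out: dict[str, list[SpectralBand]] = {}
    for b in bands:
        out.setdefault(b.emitter_id, []).append(b)
    return out


def emitter_channel_weights(bands: Sequence[SpectralBand]) -> dict[str, dict[str, float]]:
    """Relative band-channel weights per emitter (1.0 per owned band channel)."""
    weights: dict[str, dict[str, float]] = {}
    for b in bands:
        weights.setdefault(b.emitter_id, {ch: 0.0 for ch in CHANNELS})[b.channel] = 1.0
    return weights


def check_demultiplexable(
    sequence: IlluminationSequence,
    bands: Sequence[SpectralBand] | None = None,
    crosstalk_threshold: float = CROSSTALK_THRESHOLD,
) -> None:
    """Raise :class:`DemuxInfeasibleError` if any slot's emitters collide on a
    channel (weight above ``crosstalk_threshold`` of the emitter's maximum)."""
    if bands is None:
        bands = canonical_bands()
    weights = emitter_channel_weights(bands)
    for si, slot in enumerate(sequence.slots):
        used: dict[str, str] = {}
        for eid in slot.emitter_ids:
            if eid not in weights:
                raise ValueError(f"unknown emitter {eid!r} in slot {si + 1}")
            wmax = max(weights[eid].values())
            for ch, w in weights[eid].items():
                if w > crosstalk_threshold * wmax:
                    if ch in used:
                        raise DemuxInfeasibleError(
                            f"slot {si + 1}: emitters {used[ch]!r} and {eid!r} both feed "
                            f"channel {ch}"
                        )
                    used[ch] = eid


def sequence_bands(
    sequence: IlluminationSequence, bands: Sequence[SpectralBand] | None = None
) -> list[SpectralBand]:
    """All bands produced by the sequence, in (slot, band) order."""
    if bands is None:
        bands = canonical_bands()
    by_emitter = _bands_by_emitter(bands)
    out: list[SpectralBand] = []
    for slot in sequence.slots:
        for eid in slot.emitter_ids:
            out.extend(by_emitter.get(eid, []))
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def auto_gain(
    sequence: IlluminationSequence,
    bands: Sequence[SpectralBand] | None = None,
    level: float = 0.80,
) -> float:
    """Gain such that a uniform white target yields a mean signal of
    ``level`` x full scale over the sequence's active channels (the sensor's
    level-control target)."""
    if bands is None:
        bands = canonical_bands()
    by_emitter = _bands_by_emitter(bands)
    channel_values: list[float] = []
    for slot in sequence.slots:
        per_channel = {ch: 0.0 for ch in CHANNELS}
        active = {ch: False for ch in CHANNELS}
        for eid, on in slot.emitters:
            for b in by_emitter.get(eid, []):
                per_channel[b.channel] += on  # white target: R = 1
                active[b.channel] = True
        channel_values.extend(v for ch, v in per_channel.items() if active[ch])
    if not channel_values:
        raise ValueError("sequence activates no bands")
    return level * FULL_SCALE / float(np.mean(channel_values))


#: Expected positive offset of the per-frame-deviation SNR metric relative to
#: 20*log10(mean/sigma) for Gaussian noise: E[-20*log10|Z|], Z ~ N(0,1).
SNR_GAUSSIAN_OFFSET_DB = 20.0 * (np.euler_gamma + np.log(2.0)) / 2.0 / np.log(10.0)


def noise_sigma_for_target(mean_dn: float, target_snr_db: float) -> float:
    """Additive-noise sigma (DN) so the frame-deviation SNR metric is expected
    to land at ``target_snr_db`` for a signal of ``mean_dn``."""
    return mean_dn * 10.0 ** ((SNR_GAUSSIAN_OFFSET_DB - target_snr_db) / 20.0)


def render_raw(
    band_reflectance: Mapping[float, np.ndarray],
    sequence: IlluminationSequence,
    bands: Sequence[SpectralBand] | None = None,
    gain: float | None = None,
    level_control: float | None = None,
    noise_sigma_dn: float = 0.0,
    frame_offset_sigma_dn: float = 0.0,
    dark_dn: float = DARK_LEVEL_DN,
    seed: int | None = None,
    frame_number_start: int = 0,
    quantize: bool = True,
) -> list[RawFrame]:
    """Render one sequence pass into raw 10-bit RGB frames.

    ``band_reflectance`` maps band peak (nm) to a reflectance map.  Every map
    must correspond to a band the sequence produces; conversely every band of
    an active emitter needs a map.  Channel values are the sum of the active
    bands' reflectance x on-time x gain, plus the dark level and optional
    Gaussian read noise, clipped and quantised to [0, 1023].  ``level_control``
    (e.g. 0.80) derives the gain from the white-target level instead of an
    explicit ``gain``.
    """
    if bands is None:
        bands = canonical_bands()
    if gain is None:
        gain = auto_gain(sequence, bands, level=level_control if level_control else 0.80)
    by_emitter = _bands_by_emitter(bands)

    produced = {b.peak_nm for b in sequence_bands(sequence, bands)}
    extra = set(band_reflectance) - produced
    if extra:
        raise ValueError(f"bands {sorted(extra)} nm do not appear in the sequence")

    shapes = {np.asarray(v).shape for v in band_reflectance.values()}
    if len(shapes) != 1:
        raise ValueError("all reflectance maps must share one shape")
    shape = shapes.pop()

    rng = np.random.default_rng(seed)
    frames: list[RawFrame] = []
    for si, slot in enumerate(sequence.slots):
        img = np.zeros(shape + (3,), dtype=float)
        for eid, on in slot.emitters:
            for b in by_emitter.get(eid, []):
                if b.peak_nm not in band_reflectance:
                    raise ValueError(
                        f"no reflectance map for band {b.peak_nm} nm of emitter {eid!r}"
                    )
                img[:, :, _CH_INDEX[b.channel]] += (
                    np.asarray(band_reflectance[b.peak_nm], dtype=float) * on * gain
                )
        img += dark_dn
        if noise_sigma_dn > 0:
            img += rng.normal(0.0, noise_sigma_dn, size=img.shape)
        if frame_offset_sigma_dn > 0:
            # frame-global illumination/readout fluctuation
            img += rng.normal(0.0, frame_offset_sigma_dn)
        img = np.clip(img, 0, FULL_SCALE)
        if quantize:
            img = np.rint(img).astype(np.uint16)
        frames.append(
            RawFrame(pixels=img, image_index=si + 1, frame_number=frame_number_start + si)
        )
    return frames


# ---------------------------------------------------------------------------
# demultiplexing and reflectance
# ---------------------------------------------------------------------------


def demultiplex(
    frames: Sequence[RawFrame],
    sequence: IlluminationSequence,
    bands: Sequence[SpectralBand] | None = None,
) -> dict[float, np.ndarray]:
    """Split one sequence pass into per-band intensity images.

    Within a slot, separation uses the colour channels; across slots, the
    alternating lighting.  Returns a mapping band peak (nm) -> float image.
    """
    if bands is None:
        bands = canonical_bands()
    check_demultiplexable(sequence, bands)
    by_index = {f.image_index: f for f in frames}
    missing = set(range(1, len(sequence.slots) + 1)) - set(by_index)
    if missing:
        raise IncompleteSequenceError(f"missing image indexes: {sorted(missing)}")
    by_emitter = _bands_by_emitter(bands)
    out: dict[float, np.ndarray] = {}
    for si, slot in enumerate(sequence.slots):
        frame = by_index[si + 1]
        for eid in slot.emitter_ids:
            for b in by_emitter.get(eid, []):
                out[b.peak_nm] = frame.channel(b.channel)
    return out


def reflectance(
    raw: np.ndarray, dark: np.ndarray, white: np.ndarray
) -> np.ma.MaskedArray:
    """Reflectance R = (I_raw - I_D) / (I_W - I_D), masked where I_W <= I_D."""
    raw = np.asarray(raw, dtype=float)
    dark = np.asarray(dark, dtype=float)
    white = np.asarray(white, dtype=float)
    if not (raw.shape == dark.shape == white.shape):
        raise ValueError("raw, dark and white images must share one shape")
    denom = white - dark
    invalid = denom <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (raw - dark) / denom
    return np.ma.MaskedArray(r, mask=invalid)


def reflectance_stack(
    frames: Sequence[RawFrame],
    dark_frames: Sequence[RawFrame],
    white_frames: Sequence[RawFrame],
    sequence: IlluminationSequence,
    bands: Sequence[SpectralBand] | None = None,
) -> dict[float, np.ma.MaskedArray]:
    """Demultiplex raw, dark and white passes and form per-band reflectance."""
    raw_maps = demultiplex(frames, sequence, bands)
    dark_maps = demultiplex(dark_frames, sequence, bands)
    white_maps = demultiplex(white_frames, sequence, bands)
    return {
        peak: reflectance(raw_maps[peak], dark_maps[peak], white_maps[peak])
        for peak in raw_maps
    }


def switching_check(frames: Sequence[RawFrame], min_per_index: int = 10) -> dict[int, float]:
    """Mean pixel value per image index over a looped switching test.

    Used to verify LED/sensor synchronisation: with one LED lit only in slot
    2, indexes 1 and 3 should sit at the dark level and index 2 at the signal
    level.
    """
    groups: dict[int, list[float]] = {}
    for f in frames:
        groups.setdefault(f.image_index, []).append(float(np.mean(f.pixels)))
    for idx, vals in groups.items():
        if len(vals) < min_per_index:
            raise ValueError(
                f"image index {idx}: {len(vals)} frames, need >= {min_per_index}"
            )
    return {idx: float(np.mean(vals)) for idx, vals in sorted(groups.items())}


def saturated_fraction(frames: Sequence[RawFrame]) -> float:
    """Fraction of pixels at full scale across the given frames."""
    total = 0
    sat = 0
    for f in frames:
        total += f.pixels.size
        sat += int(np.count_nonzero(f.pixels >= FULL_SCALE))
    return sat / total if total else 0.0
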