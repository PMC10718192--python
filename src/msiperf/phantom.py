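"""Two-layer tissue phantom and synthetic occlusion-study generator.

The volunteer dataset behind the instrument's evaluation is private, so this
module generates a synthetic stand-in with the same statistical structure: a
forearm-skin phantom whose reflectance follows a modified Beer--Lambert model
with two layers (a thin superficial layer probed by green light, a deeper
layer probed by red/NIR light), driven through a timed venous/arterial
occlusion protocol, imaged as 10-bit raw RGB frame sequences, and paired with
co-registered reference parameter images (THI, NIR PI, StO2 in [0, 1]) of the
kind a clinical hyperspectral camera produces.

Forward model per band (peak wavelength lambda, layer l):

    R(lambda) = exp(-(eps_mix(lambda) * C_tHb * L_l + G))
    eps_mix   = SO2_l * eps_HbO2 + (1 - SO2_l) * eps_HHb

with C_tHb the total hemoglobin concentration (mM), L_l an effective optical
path length per layer (mm), SO2_l the layer oxygen saturation and G a
wavelength-independent scattering/coupling loss.  The model is deliberately
minimal: it reproduces the *orderings* the analysis pipeline relies on
(absorption up => reflectance down; opposing HbO2/HHb absorption around the
800 nm isosbestic point), not absolute radiometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .spectral import SpectralBand, canonical_bands

__all__ = [
    "ChromophoreTable",
    "default_chromophores",
    "TissueState",
    "OcclusionProtocol",
    "default_protocol",
    "Severity",
    "ReferenceImage",
    "AffineMap",
    "DEFAULT_REFERENCE_MAPPING",
    "REFERENCE_PARAMETERS",
    "occlusion_timecourse",
    "simulate_band_reflectance",
    "reference_parameters",
    "baseline_state",
    "draw_subject",
    "StudyDesign",
    "run_synthetic_study",
]


# ---------------------------------------------------------------------------
# chromophores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChromophoreTable:
    """Molar extinction spectra of HbO2 and HHb on a wavelength grid.

    Units: 1/(mM * mm).  The default table is a coarse rendition of the
    textbook hemoglobin spectra with the features the pipeline depends on:
    strong green absorption (double HbO2 peak region), HHb >> HbO2 in the red,
    an isosbestic crossing near 800 nm, and HbO2 > HHb above ~810 nm.
    """

    wavelengths_nm: np.ndarray
    eps_hbo2: np.ndarray
    eps_hhb: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        eo = np.asarray(self.eps_hbo2, dtype=float)
        ed = np.asarray(self.eps_hhb, dtype=float)
        if not (wl.shape == eo.shape == ed.shape):
            raise ValueError("chromophore arrays must share one shape")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(eo <= 0) or np.any(ed <= 0):
            raise ValueError("extinction spectra must be positive")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "eps_hbo2", eo)
        object.__setattr__(self, "eps_hhb", ed)

    def eps_at(self, wavelength_nm: float) -> tuple[float, float]:
        """(eps_HbO2, eps_HHb) at ``wavelength_nm`` by linear interpolation."""
        wl = self.wavelengths_nm
        if not (wl[0] <= wavelength_nm <= wl[-1]):
            raise ValueError(f"{wavelength_nm} nm outside chromophore grid [{wl[0]}, {wl[-1]}]")
        return (
            float(np.interp(wavelength_nm, wl, self.eps_hbo2)),
            float(np.interp(wavelength_nm, wl, self.eps_hhb)),
        )

    def eps_mix(self, wavelength_nm: float, so2: np.ndarray | float) -> np.ndarray | float:
        """Saturation-weighted extinction: so2*eps_HbO2 + (1-so2)*eps_HHb."""
        eo, ed = self.eps_at(wavelength_nm)
        return so2 * eo + (1.0 - so2) * ed

    def isosbestic_nm(self, low: float = 790.0, high: float = 810.0) -> float:
        """Grid wavelength in [low, high] where |eps_HbO2 - eps_HHb| is minimal."""
        wl = self.wavelengths_nm
        sel = (wl >= low) & (wl <= high)
        if not np.any(sel):
            raise ValueError(f"no grid points within [{low}, {high}] nm")
        diff = np.abs(self.eps_hbo2 - self.eps_hhb)[sel]
        return float(wl[sel][int(np.argmin(diff))])


# Coarse extinction table in 1/(mM*mm) at the canonical band peaks plus the
# 800 nm isosbestic point.  Magnitudes are scaled so that physiological
# hemoglobin concentrations (~0.05-0.2 mM) and mm-scale path lengths give
# mid-range baseline reflectances.
_EPS_TABLE = (
    # nm     HbO2    HHb
    (404.0, 28.00, 35.00),
    (426.0, 12.00, 28.00),
    (450.0, 6.20, 10.40),
    (503.0, 2.00, 2.00),
    (519.0, 2.60, 2.20),
    (532.0, 4.50, 3.80),
    (537.0, 5.00, 4.40),
    (580.0, 5.00, 3.70),
    (590.0, 2.80, 3.50),
    (600.0, 0.320, 1.500),
    (635.0, 0.120, 0.550),
    (663.0, 0.032, 0.310),
    (762.0, 0.059, 0.130),
    (800.0, 0.0800, 0.0800),
    (811.0, 0.086, 0.075),
    (863.0, 0.110, 0.070),
    (957.0, 0.130, 0.065),
)


def default_chromophores() -> ChromophoreTable:
    """The package's built-in hemoglobin extinction table (synthetic, coarse)."""
    arr = np.array(_EPS_TABLE, dtype=float)
    return ChromophoreTable(arr[:, 0], arr[:, 1], arr[:, 2])


# ---------------------------------------------------------------------------
# tissue state
# ---------------------------------------------------------------------------


@dataclass
class TissueState:
    """Per-pixel physiological state of the two-layer phantom.

    thb: total hemoglobin concentration map (mM); so2_deep / so2_sup: oxygen
    saturation of the deep and superficial layer (fraction in [0, 1]);
    scatter_loss: wavelength-independent attenuation offset G; path_mm:
    effective optical path length per layer (mm).
    """

    thb: np.ndarray
    so2_deep: np.ndarray
    so2_sup: np.ndarray
    scatter_loss: float = 0.25
    path_mm: dict = field(default_factory=lambda: {"sup": 0.6, "deep": 5.0})

    def __post_init__(self) -> None:
        self.thb = np.asarray(self.thb, dtype=float)
        self.so2_deep = np.asarray(self.so2_deep, dtype=float)
        self.so2_sup = np.asarray(self.so2_sup, dtype=float)
        if not (self.thb.shape == self.so2_deep.shape == self.so2_sup.shape):
            raise ValueError("all state maps must share one shape")
        if np.any(self.thb <= 0):
            raise ValueError("thb must be positive everywhere")
        for name in ("so2_deep", "so2_sup"):
            arr = getattr(self, name)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.thb.shape


# ---------------------------------------------------------------------------
# occlusion protocol and trajectories
# ---------------------------------------------------------------------------

PHASE_LABELS = ("baseline", "venous", "reperfusion1", "arterial", "reperfusion2")


@dataclass(frozen=True)
class OcclusionProtocol:
    """Timed occlusion measurement protocol.

    Defaults: 2 min normal perfusion, 2 min venous occlusion, 5 min
    reperfusion, 2 min arterial occlusion, 5 min reperfusion (16 min total);
    600 raw frames and one reference parameter block acquired per minute.
    """

    phases: tuple[tuple[str, float], ...] = (
        ("baseline", 2.0),
        ("venous", 2.0),
        ("reperfusion1", 5.0),
        ("arterial", 2.0),
        ("reperfusion2", 5.0),
    )
    frames_per_min: int = 600
    reference_blocks_per_min: int = 1

    def __post_init__(self) -> None:
        for label, dur in self.phases:
            if label not in PHASE_LABELS:
                raise ValueError(f"unknown phase label {label!r}")
            if dur <= 0:
                raise ValueError("phase durations must be positive")
        if self.frames_per_min < 1 or self.reference_blocks_per_min < 1:
            raise ValueError("per-minute counts must be >= 1")

    @property
    def total_min(self) -> float:
        return float(sum(d for _, d in self.phases))

    def boundaries_min(self) -> np.ndarray:
        """Cumulative phase end times in minutes."""
        return np.cumsum([d for _, d in self.phases])

    def phase_at(self, t_min: float) -> str:
        if t_min < 0 or t_min > self.total_min:
            raise ValueError(f"t={t_min} outside protocol [0, {self.total_min}] min")
        for (label, _), end in zip(self.phases, self.boundaries_min()):
            if t_min <= end:
                return label
        return self.phases[-1][0]


def default_protocol() -> OcclusionProtocol:
    return OcclusionProtocol()


@dataclass(frozen=True)
class Severity:
    """Per-subject occlusion effect sizes (fractions in [0, 1]).

    venous_thb: fractional hemoglobin pooling rise during venous occlusion;
    venous_so2: fractional deep-saturation drop during venous occlusion (the
    superficial layer desaturates at half that rate); arterial_so2_deep /
    arterial_so2_sup: fractional saturation drops during arterial occlusion;
    relax_tau_min: reperfusion relaxation time constant.
    """

    venous_thb: float = 0.45
    venous_so2: float = 0.15
    arterial_so2_deep: float = 0.55
    arterial_so2_sup: float = 0.50
    relax_tau_min: float = 0.8

    def __post_init__(self) -> None:
        for name in ("venous_thb", "venous_so2", "arterial_so2_deep", "arterial_so2_sup"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.relax_tau_min <= 0:
            raise ValueError("relax_tau_min must be positive")


def _trajectory_multipliers(
    protocol: OcclusionProtocol, severity: Severity, times_min: np.ndarray
) -> dict[str, np.ndarray]:
    """Piecewise-smooth global multipliers for thb / so2_deep / so2_sup.

    Occlusion phases ramp linearly toward their phase target; reperfusion
    phases relax exponentially back to 1 (the baseline).  Multipliers are
    continuous across phase boundaries.
    """
    targets = {
        "baseline": {"thb": None, "so2_deep": None, "so2_sup": None},
        "venous": {
            "thb": 1.0 + severity.venous_thb,
            "so2_deep": 1.0 - severity.venous_so2,
            "so2_sup": 1.0 - 0.5 * severity.venous_so2,
        },
        "arterial": {
            "thb": None,  # cuff above arterial pressure: inflow and outflow stop
            "so2_deep": 1.0 - severity.arterial_so2_deep,
            "so2_sup": 1.0 - severity.arterial_so2_sup,
        },
    }
    out = {k: np.empty_like(times_min, dtype=float) for k in ("thb", "so2_deep", "so2_sup")}
    starts = np.concatenate([[0.0], protocol.boundaries_min()[:-1]])
    # state at the start of the current phase
    current = {"thb": 1.0, "so2_deep": 1.0, "so2_sup": 1.0}
    for (label, dur), t0 in zip(protocol.phases, starts):
        t1 = t0 + dur
        sel = (times_min >= t0) & (times_min <= t1)
        tt = times_min[sel]
        nxt = {}
        for key in out:
            v0 = current[key]
            if label.startswith("reperfusion"):
                vals = 1.0 + (v0 - 1.0) * np.exp(-(tt - t0) / severity.relax_tau_min)
                v_end = 1.0 + (v0 - 1.0) * np.exp(-dur / severity.relax_tau_min)
            else:
                tgt = targets.get(label, {}).get(key)
                if tgt is None:  # hold
                    vals = np.full_like(tt, v0)
                    v_end = v0
                else:
                    vals = v0 + (tgt - v0) * (tt - t0) / dur
                    v_end = tgt
            out[key][sel] = vals
            nxt[key] = v_end
        current = nxt
    return out


def occlusion_timecourse(
    protocol: OcclusionProtocol,
    baseline: TissueState,
    severity: Severity | None = None,
    times_min: Sequence[float] | None = None,
) -> tuple[np.ndarray, list[TissueState]]:
    """Tissue states along the occlusion protocol.

    Returns ``(times, states)`` where ``times`` defaults to the reference
    block times (end of each acquisition minute).  The trajectory is anchored
    at the baseline state at t=0; venous occlusion pools hemoglobin (thb up,
    saturations mildly down), arterial occlusion desaturates both layers at
    roughly constant thb, and reperfusion relaxes exponentially to baseline.
    Deterministic: all randomness (subject baselines, severities, textures)
    lives in :func:`draw_subject`.
    """
    if severity is None:
        severity = Severity()
    if times_min is None:
        n_blocks = int(round(protocol.total_min * protocol.reference_blocks_per_min))
        times_min = np.arange(1, n_blocks + 1, dtype=float) / protocol.reference_blocks_per_min
    times = np.asarray(times_min, dtype=float)
    if np.any(times < 0) or np.any(times > protocol.total_min):
        raise ValueError("requested times fall outside the protocol")
    mult = _trajectory_multipliers(protocol, severity, times)
    states = []
    for i in range(times.size):
        states.append(
            TissueState(
                thb=baseline.thb * mult["thb"][i],
                so2_deep=np.clip(baseline.so2_deep * mult["so2_deep"][i], 0.0, 1.0),
                so2_sup=np.clip(baseline.so2_sup * mult["so2_sup"][i], 0.0, 1.0),
                scatter_loss=baseline.scatter_loss,
                path_mm=dict(baseline.path_mm),
            )
        )
    return times, states


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def simulate_band_reflectance(
    state: TissueState,
    band: SpectralBand,
    chromophores: ChromophoreTable | None = None,
    layer: str | None = None,
) -> np.ndarray:
    """Modified Beer--Lambert reflectance map for one band.

    The sensing layer defaults to the band's penetration-depth class
    (peak < 620 nm -> superficial, else deep).
    """
    if chromophores is None:
        chromophores = default_chromophores()
    if layer is None:
        layer = band.depth_class
    if layer not in ("sup", "deep"):
        raise ValueError("layer must be 'sup' or 'deep'")
    so2 = state.so2_sup if layer == "sup" else state.so2_deep
    eps = chromophores.eps_mix(band.peak_nm, so2)
    absorbance = eps * state.thb * state.path_mm[layer] + state.scatter_loss
    return np.exp(-absorbance)


# ---------------------------------------------------------------------------
# reference parameter images
# ---------------------------------------------------------------------------

REFERENCE_PARAMETERS = ("THI", "NIR_PI", "StO2")


@dataclass(frozen=True)
class AffineMap:
    slope: float
    intercept: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.slope * x + self.intercept


#: Default affine maps from simulated physiology into the reference scales.
#: Chosen so that the default study population (baselines, textures and
#: occlusion excursions below) stays inside the value ranges a clinical HSI
#: reference produces on this protocol: THI 0.031-0.907, NIR PI 0.400-0.797,
#: StO2 0.274-0.881, with StO2 mostly high (mode ~ 0.8).
DEFAULT_REFERENCE_MAPPING: dict[str, AffineMap] = {
    "THI": AffineMap(4.0, -0.12),  # from thb (mM)
    "NIR_PI": AffineMap(0.55, 0.36),  # from so2_deep
    "StO2": AffineMap(0.92, 0.05),  # from so2_sup
}


@dataclass(frozen=True)
class ReferenceImage:
    """One co-registered reference parameter image (values in [0, 1])."""

    parameter: str
    values: np.ndarray
    block_index: int = 0

    def __post_init__(self) -> None:
        if self.parameter not in REFERENCE_PARAMETERS:
            raise ValueError(f"parameter must be one of {REFERENCE_PARAMETERS}")
        vals = np.asarray(self.values, dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("reference values must lie in [0, 1]")
        object.__setattr__(self, "values", vals)


def reference_parameters(
    state: TissueState,
    mapping: Mapping[str, AffineMap] | None = None,
    block_index: int = 0,
) -> dict[str, ReferenceImage]:
    """Reference parameter images for one tissue state.

    THI is affine in total hemoglobin, NIR PI in deep-layer saturation and
    StO2 in superficial saturation; outputs are clipped to [0, 1].
    """
    if mapping is None:
        mapping = DEFAULT_REFERENCE_MAPPING
    sources = {"THI": state.thb, "NIR_PI": state.so2_deep, "StO2": state.so2_sup}
    return {
        p: ReferenceImage(p, np.clip(mapping[p](sources[p]), 0.0, 1.0), block_index)
        for p in REFERENCE_PARAMETERS
    }


# ---------------------------------------------------------------------------
# subjects and the full study
# ---------------------------------------------------------------------------


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma_px: float) -> np.ndarray:
    """Zero-mean, unit-std smooth random field (low-frequency tissue texture)."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma=sigma_px, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def baseline_state(
    rng: np.random.Generator,
    shape: tuple[int, int] = (64, 64),
    thb0: float | None = None,
    so2_deep0: float | None = None,
    so2_sup0: float | None = None,
) -> TissueState:
    """Draw a per-subject baseline state with smooth spatial texture.

    Subject-level baselines: thb ~ U(0.06, 0.10) mM, deep SO2 ~ U(0.55, 0.70),
    superficial SO2 ~ U(0.78, 0.84) (high, matching the mostly well-perfused
    fingers the reference device sees at rest).  Texture: +-20% (thb) and
    +-5% (saturations), low-frequency.
    """
    if thb0 is None:
        thb0 = rng.uniform(0.06, 0.10)
    if so2_deep0 is None:
        so2_deep0 = rng.uniform(0.55, 0.70)
    if so2_sup0 is None:
        so2_sup0 = rng.uniform(0.78, 0.84)
    sigma_px = max(2.0, min(shape) / 8.0)
    tex_thb = np.clip(0.08 * _smooth_field(rng, shape, sigma_px), -0.2, 0.2)
    tex_sd = np.clip(0.02 * _smooth_field(rng, shape, sigma_px), -0.05, 0.05)
    tex_ss = np.clip(0.02 * _smooth_field(rng, shape, sigma_px), -0.05, 0.05)
    return TissueState(
        thb=thb0 * (1.0 + tex_thb),
        so2_deep=np.clip(so2_deep0 * (1.0 + tex_sd), 0.0, 1.0),
        so2_sup=np.clip(so2_sup0 * (1.0 + tex_ss), 0.0, 1.0),
    )


def draw_subject(
    rng: np.random.Generator, shape: tuple[int, int] = (64, 64)
) -> tuple[TissueState, Severity]:
    """Draw one subject's baseline state and occlusion severities."""
    state = baseline_state(rng, shape)
    severity = Severity(
        venous_thb=rng.uniform(0.30, 0.60),
        venous_so2=rng.uniform(0.10, 0.20),
        arterial_so2_deep=rng.uniform(0.40, 0.70),
        arterial_so2_sup=rng.uniform(0.40, 0.60),
        relax_tau_min=rng.uniform(0.6, 1.0),
    )
    return state, severity


@dataclass(frozen=True)
class StudyDesign:
    """Study size: m measurements per participant, p participants per
    measurement distance, d distances."""

    measurements_per_participant: int = 16
    participants_per_distance: int = 4
    distances_mm: tuple[float, ...] = (35.0, 45.0, 55.0)

    def __post_init__(self) -> None:
        if self.measurements_per_participant < 1 or self.participants_per_distance < 1:
            raise ValueError("design counts must be >= 1")
        if len(self.distances_mm) < 1:
            raise ValueError("at least one measurement distance required")

    @property
    def n_measurements_per_parameter(self) -> int:
        return (
            self.measurements_per_participant
            * self.participants_per_distance
            * len(self.distances_mm)
        )


def run_synthetic_study(
    design: StudyDesign | None = None,
    protocol: OcclusionProtocol | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    parameters: Sequence[str] = REFERENCE_PARAMETERS,
    target_snr_db: float | None = 30.0,
    reference_mode: str = "tissue",
    snr_frames: int = 200,
) -> "StudyDataset":
    """Generate the full synthetic occlusion study.

    One protocol run per (parameter, distance, participant); each run yields
    ``measurements_per_participant`` measurements (one per reference block,
    i.e. per acquisition minute under the defaults), giving m*p*d measurements
    per parameter.  Distances modulate only a global intensity gain tuned for
    45 mm.  Deterministic for a fixed seed.

    ``reference_mode`` selects how reference parameter images are produced:
    "tissue" (default) maps the physiological state affinely into the
    reference scales; "affine-rr" defines the reference as an affine function
    of the noise-free reflectance ratio, which makes the downstream linear
    calibration exact by construction (used to validate the pipeline itself).
    """
    # imported here: acquisition/perfusion build on this module's types
    from . import acquisition, perfusion

    if design is None:
        design = StudyDesign()
    if protocol is None:
        protocol = default_protocol()
    if reference_mode not in ("tissue", "affine-rr"):
        raise ValueError("reference_mode must be 'tissue' or 'affine-rr'")

    bands = canonical_bands()
    selections = perfusion.default_selections()
    sequences = perfusion.default_sequences()
    chrom = default_chromophores()

    m = design.measurements_per_participant
    block_times = protocol.total_min * np.arange(1, m + 1) / m

    measurements: list[Measurement] = []
    participants: list[dict] = []
    references: dict[tuple[str, float], dict] = {}
    pid = 0
    for param_idx, param in enumerate(parameters):
        msi_param = perfusion.MSI_FOR_REFERENCE[param]
        selection = selections[msi_param]
        sequence = sequences[msi_param]
        seq_bands = acquisition.sequence_bands(sequence, bands)
        for di, dist in enumerate(design.distances_mm):
            gain = acquisition.auto_gain(sequence, bands) * 45.0 / dist
            key = (param, dist)
            if key not in references:
                white_maps = {b.peak_nm: np.ones(shape) for b in seq_bands}
                dark_maps = {b.peak_nm: np.zeros(shape) for b in seq_bands}
                references[key] = {
                    "white": acquisition.render_raw(white_maps, sequence, bands, gain=gain),
                    "dark": acquisition.render_raw(dark_maps, sequence, bands, gain=0.0),
                    "gain": gain,
                }
            for pj in range(design.participants_per_distance):
                pid += 1
                prng = np.random.default_rng([seed, param_idx, di, pj])
                sex = "male" if prng.uniform() < 22.0 / 36.0 else "female"
                age = int(prng.integers(18, 53))
                base, severity = draw_subject(prng, shape)
                participants.append(
                    {
                        "participant_id": f"P{pid:03d}",
                        "parameter": param,
                        "distance_mm": dist,
                        "sex": sex,
                        "age": age,
                    }
                )
                times, states = occlusion_timecourse(protocol, base, severity, block_times)
                for mi, (t, st) in enumerate(zip(times, states)):
                    refl = {
                        b.peak_nm: simulate_band_reflectance(st, b, chrom) for b in seq_bands
                    }
                    rr_truth = perfusion.reflectance_ratio(refl, selection)
                    noise = (
                        None
                        if target_snr_db is None
                        else acquisition.noise_sigma_for_target(
                            mean_dn=0.5 * gain, target_snr_db=target_snr_db
                        )
                    )
                    frame_seed = int(prng.integers(0, 2**31 - 1))
                    frames = acquisition.render_raw(
                        refl,
                        sequence,
                        bands,
                        gain=gain,
                        noise_sigma_dn=noise or 0.0,
                        seed=frame_seed,
                        frame_number_start=3 * mi,
                    )
                    if reference_mode == "tissue":
                        ref = reference_parameters(st, block_index=mi + 1)[param]
                    else:
                        rr_arr = np.asarray(rr_truth, dtype=float)
                        lo, hi = rr_arr.min(), rr_arr.max()
                        amap = _AFFINE_RR_MAPPING[param]
                        ref = ReferenceImage(
                            param, np.clip(amap(rr_arr), 0.0, 1.0), block_index=mi + 1
                        )
                    measurements.append(
                        Measurement(
                            parameter=param,
                            msi_parameter=msi_param,
                            participant_id=f"P{pid:03d}",
                            sex=sex,
                            age=age,
                            distance_mm=dist,
                            minute=mi + 1,
                            t_min=float(t),
                            phase=protocol.phase_at(float(t)),
                            frames=frames,
                            reference=ref,
                            rr_truth=np.asarray(rr_truth, dtype=float),
                        )
                    )
    # dedicated static SNR acquisition (bench characterisation at 45 mm,
    # level control 80%): repeated noisy frames per canonical band
    snr_series: dict[float, np.ndarray] = {}
    if snr_frames >= 2:
        srng = np.random.default_rng([seed, 999])
        snr_state, _ = draw_subject(srng, shape)
        for b in bands:
            snr_series[b.peak_nm] = render_snr_series(
                snr_state,
                b,
                n_frames=snr_frames,
                target_snr_db=target_snr_db if target_snr_db is not None else 30.0,
                seed=int(srng.integers(0, 2**31 - 1)),
                chromophores=chrom,
            )
    return StudyDataset(
        design=design,
        protocol=protocol,
        seed=seed,
        shape=shape,
        parameters=tuple(parameters),
        reference_mode=reference_mode,
        measurements=measurements,
        participants=participants,
        references=references,
        snr_series=snr_series,
    )


def render_snr_series(
    state: TissueState,
    band: SpectralBand,
    n_frames: int = 60,
    target_snr_db: float = 30.0,
    gain: float = 0.8 * 1023.0,
    seed: int | None = None,
    chromophores: ChromophoreTable | None = None,
) -> np.ndarray:
    """Repeated noisy acquisitions of a static scene for SNR evaluation.

    The noise model has a per-pixel component and a frame-global fluctuation
    component, both sized so the frame-deviation SNR metric is expected at
    ``target_snr_db`` (the global component dominates the scalar metric, the
    pixel component the spatially resolved one).  Returns (N, H, W) uint16.
    """
    from .acquisition import DARK_LEVEL_DN, FULL_SCALE, noise_sigma_for_target

    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    refl = simulate_band_reflectance(state, band, chromophores)
    signal = gain * refl + DARK_LEVEL_DN
    mean_dn = float(signal.mean())
    sigma = noise_sigma_for_target(mean_dn, target_snr_db)
    rng = np.random.default_rng(seed)
    frames = (
        signal[None]
        + rng.normal(0.0, sigma, size=(n_frames,) + signal.shape)  # pixel noise
        + rng.normal(0.0, sigma, size=(n_frames, 1, 1))  # frame-global noise
    )
    return np.rint(np.clip(frames, 0, FULL_SCALE)).astype(np.uint16)


#: Affine maps applied to the noise-free RR in "affine-rr" reference mode.
#: Slopes/intercepts keep the resulting reference values within (0, 1) for
#: the default population (RR ranges checked in the test-suite).
_AFFINE_RR_MAPPING: dict[str, AffineMap] = {
    "THI": AffineMap(-1.2, 1.2),  # hemoglobin RR falls as thb rises
    "NIR_PI": AffineMap(0.55, 0.10),
    "StO2": AffineMap(1.10, -0.15),
}


@dataclass
class Measurement:
    """One quantitative measurement: the last raw frame sequence of an
    acquisition block plus its co-registered reference image."""

    parameter: str
    msi_parameter: str
    participant_id: str
    sex: str
    age: int
    distance_mm: float
    minute: int
    t_min: float
    phase: str
    frames: list
    reference: ReferenceImage
    rr_truth: np.ndarray


@dataclass
class StudyDataset:
    design: StudyDesign
    protocol: OcclusionProtocol
    seed: int
    shape: tuple[int, int]
    parameters: tuple[str, ...]
    reference_mode: str
    measurements: list[Measurement]
    participants: list[dict]
    #: per (parameter, distance): white/dark reference frames and the gain
    references: dict
    #: per band peak: (N, H, W) static SNR acquisition stack
    snr_series: dict = field(default_factory=dict)

    def measurements_for(self, parameter: str) -> list[Measurement]:
        return [m for m in self.measurements if m.parameter == parameter]

    def manifest(self) -> dict:
        """JSON-serialisable study manifest (counts, design, protocol)."""
        per_param = {
            p: len(self.measurements_for(p)) for p in self.parameters
        }
        return {
            "seed": self.seed,
            "shape": list(self.shape),
            "reference_mode": self.reference_mode,
            "design": {
                "measurements_per_participant": self.design.measurements_per_participant,
                "participants_per_distance": self.design.participants_per_distance,
                "distances_mm": list(self.design.distances_mm),
                "n_measurements_per_parameter": self.design.n_measurements_per_parameter,
            },
            "protocol": {
                "phases": [[label, dur] for label, dur in self.protocol.phases],
                "total_min": self.protocol.total_min,
                "frames_per_min": self.protocol.frames_per_min,
                "reference_blocks_per_min": self.protocol.reference_blocks_per_min,
                "frames_per_run": int(
                    round(self.protocol.frames_per_min * self.protocol.total_min)
                ),
            },
            "parameters": list(self.parameters),
            "n_participants": len(self.participants),
            "participants": self.participants,
            "n_measurements": {**per_param, "total": len(self.measurements)},
        }
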