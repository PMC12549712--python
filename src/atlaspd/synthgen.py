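"""Seeded synthetic fNIRS cohort generator.

Emits raw dual-wavelength intensity so the full preprocessing chain
(optical density, motion repair, quality gating, Beer-Lambert inversion)
is exercised end to end.  Each subject's evoked response is a boxcar task
regressor convolved with a canonical double-gamma hemodynamic response
function, scaled by a class- and region-dependent HbO amplitude, summed
with physiological oscillations (cardiac, respiratory, Mayer waves),
random-walk drift, white noise, motion transients, and occasional bad or
missing channels, then forward-projected through the same modified
Beer-Lambert model the preprocessing chain inverts.

The class structure encodes the prefrontal compensation picture of early
Parkinson's disease: stage-1 patients show frontal-polar hyperactivation
relative to controls, stage-2 patients an attenuated and delayed response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .design import BlockDesign, default_design
from .layout import ChannelLayout, default_layout
from . import optics

__all__ = [
    "LABELS",
    "make_hrf",
    "GroupEffectProfile",
    "NoiseProfile",
    "OpticalRecording",
    "SubjectRecord",
    "simulate_subject",
    "simulate_cohort",
]

LABELS: tuple[str, ...] = ("HC", "HY1", "HY2")

_FPC = ("L-FPC", "R-FPC")


def make_hrf(
    peak_s: float = 5.5,
    undershoot_s: float = 15.0,
    sampling_hz: float = 100.0,
    duration_s: float = 30.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response kernel.

    Difference of two gamma densities with the main lobe peaking at
    ``peak_s`` (to within one sample) and the undershoot near
    ``undershoot_s``; the kernel maximum is scaled to 1.

    Parameters
    ----------
    peak_s : float
        Time of the positive peak, seconds.  Physiological values are 5-6 s.
    undershoot_s : float
        Time of the (negative) undershoot extremum, seconds.
    sampling_hz : float
        Output sampling rate.
    duration_s : float
        Kernel support length.
    undershoot_ratio : float
        Amplitude of the undershoot gamma relative to the main gamma.
    """
    if not (0 < peak_s < undershoot_s):
        raise ValueError("require 0 < peak_s < undershoot_s")
    if sampling_hz <= 0 or duration_s <= 0:
        raise ValueError("sampling_hz and duration_s must be positive")

    from scipy.stats import gamma as gamma_dist

    fine_hz = max(sampling_hz, 1000.0)
    t_fine = np.arange(int(round(duration_s * fine_hz))) / fine_hz

    def kernel(a1: float) -> np.ndarray:
        g1 = gamma_dist.pdf(t_fine, a1, scale=1.0)
        g2 = gamma_dist.pdf(t_fine, undershoot_s + 1.0, scale=1.0)
        g1 = g1 / g1.max()
        g2 = g2 / g2.max()
        return g1 - undershoot_ratio * g2

    # Subtracting the undershoot shifts the main peak slightly; adjust the
    # main gamma's shape so the realized argmax lands on peak_s.
    a1 = peak_s + 1.0
    for _ in range(40):
        k = kernel(a1)
        t_star = t_fine[int(np.argmax(k))]
        err = peak_s - t_star
        if abs(err) < 0.25 / fine_hz:
            break
        a1 += err
    k = kernel(a1)

    step = int(round(fine_hz / sampling_hz))
    if step > 1:
        k = k[::step]
    else:
        t = np.arange(int(round(duration_s * sampling_hz))) / sampling_hz
        k = np.interp(t, t_fine, k)
    return k / k.max()


@dataclass(frozen=True)
class GroupEffectProfile:
    """Per-class, per-region task-evoked response parameters.

    ``amplitude_um[label][region]`` is the evoked HbO amplitude in uM,
    ``latency_shift_s[label]`` delays the whole response, and
    ``variability[label]`` is the fractional between-channel amplitude sd.
    ``active_channels``, when set, restricts the evoked signal to those
    channels (all other channels receive zero task amplitude).
    ``hbr_ratio`` scales the evoked HbR response relative to HbO (the
    typical inverted response).
    """

    amplitude_um: dict[str, dict[str, float]]
    latency_shift_s: dict[str, float]
    variability: dict[str, float]
    active_channels: frozenset[str] | None = None
    hbr_ratio: float = -1.0 / 3.0

    def __post_init__(self) -> None:
        for label, per_region in self.amplitude_um.items():
            for region, amp in per_region.items():
                if not np.isfinite(amp):
                    raise ValueError(f"non-finite amplitude for {label}/{region}")
        for label, v in self.variability.items():
            if v < 0:
                raise ValueError(f"variability must be >= 0 (got {v} for {label})")

    @classmethod
    def default(cls) -> "GroupEffectProfile":
        """Moderate class separation.

        Stage-1 patients show frontal-polar hyperactivation with
        compensatory recruitment of DLPFC/BA8; stage-2 patients an
        attenuated, delayed response.  The spatial recruitment pattern and
        response latency carry class information that survives per-channel
        normalization; absolute amplitudes alone would not.
        """
        def amp(fpc, mfpc, dlpfc, ba8):
            return {"L-FPC": fpc, "R-FPC": fpc, "mFPC": mfpc,
                    "L-DLPFC": dlpfc, "R-DLPFC": dlpfc, "BA8": ba8}
        return cls(
            amplitude_um={
                "HC": amp(0.30, 0.25, 0.08, 0.05),
                "HY1": amp(0.55, 0.35, 0.30, 0.20),
                "HY2": amp(0.12, 0.12, 0.15, 0.05),
            },
            latency_shift_s={"HC": 0.0, "HY1": 1.0, "HY2": 2.5},
            variability={"HC": 0.15, "HY1": 0.15, "HY2": 0.15},
        )

    @classmethod
    def high_snr(cls) -> "GroupEffectProfile":
        """Widely separated classes with low variability, for learnability
        and robustness studies."""
        def amp(fpc, mfpc, dlpfc, ba8):
            return {"L-FPC": fpc, "R-FPC": fpc, "mFPC": mfpc,
                    "L-DLPFC": dlpfc, "R-DLPFC": dlpfc, "BA8": ba8}
        return cls(
            amplitude_um={
                "HC": amp(0.50, 0.40, 0.04, 0.04),
                "HY1": amp(0.90, 0.60, 0.50, 0.40),
                "HY2": amp(0.08, 0.10, 0.15, 0.04),
            },
            latency_shift_s={"HC": 0.0, "HY1": 1.0, "HY2": 3.5},
            variability={"HC": 0.05, "HY1": 0.05, "HY2": 0.05},
        )

    def restricted_to(self, channels) -> "GroupEffectProfile":
        """Copy with the evoked signal confined to ``channels``."""
        return replace(self, active_channels=frozenset(channels))

    def scaled(self, factor: float) -> "GroupEffectProfile":
        """Copy with every evoked amplitude multiplied by ``factor``."""
        amps = {lab: {r: a * factor for r, a in per.items()}
                for lab, per in self.amplitude_um.items()}
        return replace(self, amplitude_um=amps)


@dataclass(frozen=True)
class NoiseProfile:
    """Physiological and instrumental noise parameters.

    Oscillation amplitudes and the white-noise sd are in uM (concentration
    space); motion transients are added in intensity space as fractional,
    exponentially decaying deflections.  ``drift_scale_um`` is the standard
    deviation of the random-walk increment per second.
    """

    cardiac_hz: float = 1.1
    cardiac_amp_um: float = 0.04
    respiratory_hz: float = 0.25
    respiratory_amp_um: float = 0.03
    mayer_hz: float = 0.1
    mayer_amp_um: float = 0.05
    drift_scale_um: float = 0.01
    white_sd_um: float = 0.05
    motion_rate_per_min: float = 0.5
    motion_amp_frac: float = 0.05
    motion_tau_s: float = 1.5
    bad_channel_p: float = 0.0
    missing_p: float = 0.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("bad_channel_p", "missing_p"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} is a probability")

    @classmethod
    def default(cls) -> "NoiseProfile":
        return cls(bad_channel_p=0.05, missing_p=1e-5)

    @classmethod
    def low(cls) -> "NoiseProfile":
        """Mild noise, no bad channels or dropouts: for high-SNR cohorts."""
        return cls(cardiac_amp_um=0.03, respiratory_amp_um=0.02,
                   mayer_amp_um=0.02, drift_scale_um=0.004,
                   white_sd_um=0.03, motion_rate_per_min=0.2)

    @classmethod
    def zero(cls) -> "NoiseProfile":
        return cls(cardiac_amp_um=0.0, respiratory_amp_um=0.0,
                   mayer_amp_um=0.0, drift_scale_um=0.0, white_sd_um=0.0,
                   motion_rate_per_min=0.0, motion_amp_frac=0.0)


@dataclass
class OpticalRecording:
    """Raw dual-wavelength intensity: channels x time x 2 wavelengths."""

    intensity: np.ndarray
    wavelengths_nm: tuple[float, float]
    sampling_hz: float
    layout: ChannelLayout
    design: BlockDesign

    def __post_init__(self) -> None:
        c, t, w = self.intensity.shape
        if c != self.layout.n_channels:
            raise ValueError("channel axis does not match layout")
        if w != 2:
            raise ValueError("expected two wavelengths")
        if t != self.design.n_samples:
            raise ValueError("time axis does not match design")
        finite = self.intensity[np.isfinite(self.intensity)]
        if finite.size and finite.min() <= 0:
            raise ValueError("intensity must be strictly positive where present")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[1]


@dataclass
class SubjectRecord:
    """One simulated subject: label, raw recording, and injected ground truth.

    ``ground_truth_amp_um`` (per-channel injected HbO task amplitude) exists
    for test oracles only and must never be consumed by classifiers.
    """

    subject_id: str
    label: str
    recording: OpticalRecording
    ground_truth_amp_um: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def _evoked_regressor(design: BlockDesign, latency_s: float, hrf: np.ndarray) -> np.ndarray:
    """Boxcar task regressor convolved with the HRF, unit peak-amplitude scale."""
    from scipy.signal import fftconvolve

    box = design.boxcar()
    if latency_s > 0:
        shift = int(round(latency_s * design.sampling_hz))
        box = np.concatenate([np.zeros(shift), box[: len(box) - shift]])
    conv = fftconvolve(box, hrf)[: len(box)]
    # normalize by the kernel sum so a sustained task block plateaus at ~1,
    # making the injected amplitude interpretable as the plateau height in uM
    plateau = hrf.sum()
    if plateau > 0:
        conv = conv / plateau
    return conv


def simulate_subject(
    label: str,
    design: BlockDesign | None = None,
    layout: ChannelLayout | None = None,
    effects: GroupEffectProfile | None = None,
    noise: NoiseProfile | None = None,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "sub-000",
    dpf: float = 6.0,
    baseline_intensity: float = 1.0,
) -> SubjectRecord:
    """Simulate one subject's raw dual-wavelength session.

    The per-channel HbO series is (boxcar (*) HRF) * amplitude + noise; HbR
    is the evoked response scaled by ``effects.hbr_ratio`` plus its own
    noise; both are forward-projected to intensity via the modified
    Beer-Lambert law.  Deterministic given ``seed``.
    """
    design = design or default_design()
    layout = layout or default_layout()
    effects = effects or GroupEffectProfile.default()
    noise = noise or NoiseProfile.default()
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(seed)

    fs = design.sampling_hz
    n = design.n_samples
    c = layout.n_channels
    t_axis = np.arange(n) / fs

    hrf = make_hrf(sampling_hz=fs)
    evoked = _evoked_regressor(design, effects.latency_shift_s[label], hrf)

    amps = np.empty(c)
    for i, ch in enumerate(layout.channel_ids):
        base = effects.amplitude_um[label][layout.region_of[ch]]
        if effects.active_channels is not None and ch not in effects.active_channels:
            base = 0.0
        amps[i] = base * (1.0 + effects.variability[label] * rng.standard_normal())

    hbo = amps[:, None] * evoked[None, :]
    hbr = effects.hbr_ratio * hbo

    # physiological oscillations: blood-volume waves move HbO and HbR in the
    # same direction (this shared cardiac pulsation is what the scalp
    # coupling index keys on); common frequency, channel-specific phase
    for freq, amp in ((noise.cardiac_hz, noise.cardiac_amp_um),
                      (noise.respiratory_hz, noise.respiratory_amp_um),
                      (noise.mayer_hz, noise.mayer_amp_um)):
        if amp > 0 and freq < fs / 2:
            phase = rng.uniform(0, 2 * np.pi, size=c)
            osc = amp * np.sin(2 * np.pi * freq * t_axis[None, :] + phase[:, None])
            hbo = hbo + osc
            hbr = hbr + 0.3 * osc
    if noise.drift_scale_um > 0:
        step = noise.drift_scale_um / np.sqrt(fs)
        hbo = hbo + np.cumsum(rng.normal(0, step, size=(c, n)), axis=1)
        hbr = hbr + np.cumsum(rng.normal(0, 0.5 * step, size=(c, n)), axis=1)
    if noise.white_sd_um > 0:
        hbo = hbo + rng.normal(0, noise.white_sd_um, size=(c, n))
        hbr = hbr + rng.normal(0, 0.5 * noise.white_sd_um, size=(c, n))

    od = optics.hemoglobin_to_od(
        hbo, hbr, dpf=dpf, distance_cm=layout.source_detector_distance_cm
    )  # (c, n, 2)
    intensity = optics.od_to_intensity(od, baseline_intensity)

    # motion transients: exponential-decay deflections in intensity space
    if noise.motion_rate_per_min > 0 and noise.motion_amp_frac > 0:
        n_events = rng.poisson(noise.motion_rate_per_min * design.total_s / 60.0, size=c)
        decay = np.exp(-np.arange(int(round(5 * noise.motion_tau_s * fs))) / (noise.motion_tau_s * fs))
        for i in range(c):
            for _ in range(n_events[i]):
                t0 = rng.integers(0, n)
                sign = rng.choice([-1.0, 1.0])
                amp = noise.motion_amp_frac * baseline_intensity * rng.uniform(0.5, 2.0)
                seg = min(len(decay), n - t0)
                intensity[i, t0:t0 + seg, :] += sign * amp * decay[:seg, None]

    # bad channels: optode decoupling -> lose shared physiology, heavy
    # independent noise per wavelength (drives SCI down), near-flat signal
    bad = rng.random(c) < noise.bad_channel_p
    for i in np.where(bad)[0]:
        flat = baseline_intensity * 0.02
        intensity[i] = flat + 0.001 * baseline_intensity * rng.standard_normal((n, 2))
        amps[i] = 0.0
    intensity = np.clip(intensity, 1e-6, None)

    if noise.missing_p > 0:
        miss = rng.random((c, n)) < noise.missing_p
        intensity[miss] = np.nan

    rec = OpticalRecording(intensity, optics.WAVELENGTHS_NM, fs, layout, design)
    return SubjectRecord(subject_id, label, rec, amps)


def simulate_cohort(
    n_per_class: int,
    task: str = "pegboard",
    design: BlockDesign | None = None,
    layout: ChannelLayout | None = None,
    effects: GroupEffectProfile | None = None,
    noise: NoiseProfile | None = None,
    seed: int = 0,
    gait_imagery_scale: float = 0.6,
) -> list[SubjectRecord]:
    """Simulate a balanced multi-subject cohort.

    ``task='gait_imagery'`` reuses the same block design with the evoked
    amplitudes scaled by ``gait_imagery_scale`` (the pilot imagery task is
    a weaker activator than the pegboard task).  Per-subject seeds are
    spawned reproducibly from ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if task not in ("pegboard", "gait_imagery"):
        raise ValueError(f"unknown task {task!r}")
    effects = effects or GroupEffectProfile.default()
    if task == "gait_imagery":
        effects = effects.scaled(gait_imagery_scale)
    children = np.random.SeedSequence(seed).spawn(3 * n_per_class)
    cohort: list[SubjectRecord] = []
    k = 0
    for label in LABELS:
        for j in range(n_per_class):
            cohort.append(simulate_subject(
                label, design, layout, effects, noise,
                seed=children[k], subject_id=f"sub-{k:03d}",
            ))
            k += 1
    return cohort
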