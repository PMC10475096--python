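"""Synthetic µECoG generator: stimulation protocols, cortical temperature
traces, discharge waveform prototypes and full multichannel recordings with
ground truth.

The generator stands in for animal recordings: it reproduces the *structure*
of the experiment (phase timing, channel groups, thermally modulated event
statistics) with simple, fully seeded stochastic models — first-order thermal
kinetics, Gaussian-shaped discharge prototypes, 1/f background noise and a
hard-core renewal event process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "Phase",
    "ProtocolTimeline",
    "ThermalParams",
    "EffectModel",
    "BackgroundParams",
    "Recording",
    "TemperatureTrace",
    "STUDY_PULSE_FREQUENCIES",
    "build_protocol",
    "simulate_temperature",
    "synth_ied",
    "simulate_recording",
    "default_layout",
]

# Pulse frequencies used in study-faithful runs (0 = continuous wave).
STUDY_PULSE_FREQUENCIES = (0.0, 1.0, 10.0, 100.0, 1000.0)

PCTRL = "PCtrl"
P2ON = "P2ON"
P4ON = "P4ON"
P4OFF = "P4OFF"

_CONTROL_S = 120.0
_ON_S = {"ISP1": 120.0, "ISP2": 240.0}
_ON_LABEL = {"ISP1": P2ON, "ISP2": P4ON}
_OFF_S = 240.0

#: Peak cortical temperature elevation (°C) near / far from the light source,
#: tabulated per pulse frequency; linear interpolation in between.
DELTA_T_NEAR_C = {0.0: 3.0, 1.0: 1.6, 10.0: 1.7, 100.0: 1.8, 1000.0: 1.5}
DELTA_T_FAR_C = {0.0: 1.5, 1.0: 0.8, 10.0: 0.85, 100.0: 0.9, 1000.0: 0.75}

#: Scale applied to the ON-phase amplitude/rate *effect* per site group;
#: Group#1 feels the full effect, Group#4 roughly 40% of it.
GROUP_EFFECT_SCALE = (1.0, 0.8, 0.6, 0.4)

_EDGE_MARGIN_S = 0.175  # keeps every 300-ms segment inside the recording
_MIN_SPACING_S = 0.350  # hard-core gap between injected events per channel


@dataclass(frozen=True)
class Phase:
    label: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ProtocolTimeline:
    """Ordered stimulation phases of one ISP session.

    One 120-s control phase followed by ``n_trials`` ON/OFF cycles.
    """

    isp_id: str
    pulse_frequency_hz: float
    n_trials: int
    phases: tuple[Phase, ...]
    duty_cycle: float = 0.5

    @property
    def duration_s(self) -> float:
        return self.phases[-1].end_s

    @property
    def on_label(self) -> str:
        return _ON_LABEL[self.isp_id]

    @property
    def on_s(self) -> float:
        return _ON_S[self.isp_id]

    @property
    def cycle_s(self) -> float:
        """Length of one ON + OFF trial cycle in seconds."""
        return self.on_s + _OFF_S

    @property
    def is_study_frequency(self) -> bool:
        return float(self.pulse_frequency_hz) in STUDY_PULSE_FREQUENCIES

    def trial_cycle(self, trial_index: int) -> tuple[Phase, Phase]:
        """(ON, OFF) phases of trial ``trial_index`` (0-based)."""
        if not 0 <= trial_index < self.n_trials:
            raise IndexError(f"trial_index {trial_index} out of range")
        on = self.phases[1 + 2 * trial_index]
        off = self.phases[2 + 2 * trial_index]
        return on, off

    def on_phases(self) -> list[Phase]:
        return [p for p in self.phases if p.label in (P2ON, P4ON)]

    def on_mask(self, times_s: np.ndarray) -> np.ndarray:
        """Boolean mask: which time points fall inside a laser-ON phase."""
        t = np.asarray(times_s, dtype=float)
        mask = np.zeros(t.shape, dtype=bool)
        for p in self.on_phases():
            mask |= (t >= p.start_s) & (t < p.end_s)
        return mask

    def phase_at(self, t: float) -> Phase:
        for p in self.phases:
            if p.start_s <= t < p.end_s:
                return p
        if t == self.duration_s:
            return self.phases[-1]
        raise ValueError(f"time {t} outside protocol [0, {self.duration_s}]")


def build_protocol(isp_id: str, pulse_frequency_hz: float, n_trials: int) -> ProtocolTimeline:
    """Build the phase timeline of one infrared stimulation session.

    ISP1 cycles are 120 s ON + 240 s OFF, ISP2 cycles 240 s ON + 240 s OFF;
    a single 120-s control phase precedes trial 1.
    """
    if isp_id not in ("ISP1", "ISP2"):
        raise ValueError(f"isp_id must be 'ISP1' or 'ISP2', got {isp_id!r}")
    if n_trials < 0 or int(n_trials) != n_trials:
        raise ValueError(f"n_trials must be a non-negative integer, got {n_trials!r}")
    if pulse_frequency_hz < 0:
        raise ValueError(f"pulse_frequency_hz must be >= 0, got {pulse_frequency_hz!r}")
    if float(pulse_frequency_hz) not in STUDY_PULSE_FREQUENCIES:
        warnings.warn(
            f"pulse frequency {pulse_frequency_hz} Hz is not one of the study "
            f"frequencies {STUDY_PULSE_FREQUENCIES}",
            stacklevel=2,
        )
    phases = [Phase(PCTRL, 0.0, _CONTROL_S)]
    on_s = _ON_S[isp_id]
    t = _CONTROL_S
    for _ in range(int(n_trials)):
        phases.append(Phase(_ON_LABEL[isp_id], t, t + on_s))
        t += on_s
        phases.append(Phase(P4OFF, t, t + _OFF_S))
        t += _OFF_S
    return ProtocolTimeline(isp_id, float(pulse_frequency_hz), int(n_trials), tuple(phases))


# ---------------------------------------------------------------------------
# Temperature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermalParams:
    """First-order thermal kinetics of the heated cortex.

    During laser ON the temperature relaxes toward ``baseline + delta_t_max``
    with time constant ``tau_heat_s``; during OFF it relaxes back to baseline
    with ``tau_cool_s``. A seeded low-frequency fluctuation is added during
    OFF phases at low pulse frequencies.
    """

    delta_t_max_near_c: float = 3.0
    delta_t_max_far_c: float = 1.5
    tau_heat_s: float = 25.0
    tau_cool_s: float = 35.0
    baseline_c: float = 36.5
    fluctuation_sd_c: float = 0.05

    def __post_init__(self):
        if self.tau_heat_s <= 0 and self.tau_heat_s != 0:
            raise ValueError("tau_heat_s must be > 0")
        if self.tau_heat_s < 0 or self.tau_cool_s < 0:
            raise ValueError("time constants must be >= 0")
        if self.delta_t_max_far_c > self.delta_t_max_near_c:
            raise ValueError("delta_t_max_far_c must not exceed delta_t_max_near_c")

    @classmethod
    def for_frequency(cls, pulse_frequency_hz: float, **overrides) -> "ThermalParams":
        """Default parameters at a given pulse frequency (0 = continuous),
        linearly interpolating the tabulated peak elevations."""
        f = float(pulse_frequency_hz)
        xs = sorted(DELTA_T_NEAR_C)
        near = float(np.interp(f, xs, [DELTA_T_NEAR_C[x] for x in xs]))
        far = float(np.interp(f, xs, [DELTA_T_FAR_C[x] for x in xs]))
        return cls(delta_t_max_near_c=near, delta_t_max_far_c=far, **overrides)


@dataclass(frozen=True)
class TemperatureTrace:
    times_s: np.ndarray
    temp_near_c: np.ndarray
    temp_far_c: np.ndarray
    sample_rate_hz: float = 6.0

    def __post_init__(self):
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not (np.all(np.isfinite(self.temp_near_c)) and np.all(np.isfinite(self.temp_far_c))):
            raise ValueError("temperatures must be finite")


def _relax(t_rel: np.ndarray, t0: float, asymptote: float, tau: float) -> np.ndarray:
    if tau <= 0:
        return np.full_like(t_rel, asymptote)
    return asymptote + (t0 - asymptote) * np.exp(-t_rel / tau)


def simulate_temperature(
    protocol: ProtocolTimeline,
    thermal_params: ThermalParams | None = None,
    seed: int = 0,
    sample_rate_hz: float = 6.0,
) -> TemperatureTrace:
    """Simulate near/far cortical temperature over the full protocol."""
    params = thermal_params or ThermalParams.for_frequency(protocol.pulse_frequency_hz)
    dt = 1.0 / sample_rate_hz
    n = int(round(protocol.duration_s * sample_rate_hz)) + 1
    times = np.arange(n) * dt

    temps = {}
    for key, d_max in (("near", params.delta_t_max_near_c), ("far", params.delta_t_max_far_c)):
        out = np.empty(n)
        cur = params.baseline_c
        for phase in protocol.phases:
            idx = np.flatnonzero((times >= phase.start_s) & (times < phase.end_s))
            if phase.label in (P2ON, P4ON):
                asym, tau = params.baseline_c + d_max, params.tau_heat_s
            else:
                asym, tau = params.baseline_c, params.tau_cool_s
            out[idx] = _relax(times[idx] - phase.start_s, cur, asym, tau)
            cur = float(_relax(np.array([phase.duration_s]), cur, asym, tau)[0])
        out[-1] = cur
        temps[key] = out

    if params.fluctuation_sd_c > 0 and 0 < protocol.pulse_frequency_hz < 10:
        # OFF-phase ambient-convection fluctuation, strongest once the cortex
        # has cooled (it never raises the heated maximum)
        rng = np.random.default_rng(seed)
        off_mask = ~protocol.on_mask(times)
        sigma_samples = 3.0 * sample_rate_hz  # ~3-s correlation time
        for key, d_max in (("near", params.delta_t_max_near_c), ("far", params.delta_t_max_far_c)):
            raw = rng.standard_normal(n)
            smooth = _gaussian_smooth(raw, sigma_samples)
            sd = smooth.std()
            if sd > 0 and d_max > 0:
                depth = np.clip(1.0 - (temps[key] - params.baseline_c) / d_max, 0.0, 1.0)
                temps[key] = temps[key] + off_mask * depth * (params.fluctuation_sd_c / sd) * smooth

    return TemperatureTrace(times, temps["near"], temps["far"], sample_rate_hz)


def _gaussian_smooth(x: np.ndarray, sigma_samples: float) -> np.ndarray:
    half = int(4 * sigma_samples)
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma_samples) ** 2)
    k /= k.sum()
    return np.convolve(x, k, mode="same")


# ---------------------------------------------------------------------------
# Discharge waveform prototypes
# ---------------------------------------------------------------------------

_SEGMENT_S = 0.300


def synth_ied(type_id: int, p2p_amplitude: float, fs: float) -> np.ndarray:
    """Prototype discharge waveform, 300 ms long, normalized peak-to-peak.

    Type 1 is biphasic: a sharp negative deflection (~20 ms half-width)
    followed by a slow positive bump (~100 ms). Type 2 is a single sharper
    negative deflection (~10 ms half-width).
    """
    if type_id not in (1, 2):
        raise ValueError(f"type_id must be 1 or 2, got {type_id!r}")
    if p2p_amplitude <= 0:
        raise ValueError(f"p2p_amplitude must be > 0, got {p2p_amplitude!r}")
    if fs < 600:
        raise ValueError(f"fs must be >= 600 Hz, got {fs!r}")
    n = int(round(_SEGMENT_S * fs))
    t = (np.arange(n) - (n - 1) / 2) / fs
    fwhm_to_sigma = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if type_id == 1:
        sigma_neg = 0.020 * fwhm_to_sigma
        sigma_slow = 0.100 * fwhm_to_sigma
        w = -np.exp(-0.5 * (t / sigma_neg) ** 2) + 0.45 * np.exp(
            -0.5 * ((t - 0.080) / sigma_slow) ** 2
        )
    else:
        sigma_neg = 0.010 * fwhm_to_sigma
        w = -np.exp(-0.5 * (t / sigma_neg) ** 2)
    w *= p2p_amplitude / (w.max() - w.min())
    return w


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectModel:
    """Signal-level consequences of the thermal stimulus.

    Multiplicative factors are applied during laser-ON phases; the effect is
    attenuated with distance via :data:`GROUP_EFFECT_SCALE`.
    """

    base_rate_hz: float = 0.6
    on_p2p_factor: float = 0.75
    on_rate_factor: float = 1.2
    type2_fraction: float = 0.5
    artifact_amp: float = 25.0
    gamma_boost: float = 2.0

    def __post_init__(self):
        if self.base_rate_hz < 0:
            raise ValueError("base_rate_hz must be >= 0")
        if self.on_p2p_factor <= 0 or self.on_rate_factor <= 0 or self.gamma_boost <= 0:
            raise ValueError("multiplicative factors must be > 0")
        if not 0 <= self.type2_fraction <= 1:
            raise ValueError("type2_fraction must be in [0, 1]")
        if self.artifact_amp < 0:
            raise ValueError("artifact_amp must be >= 0")

    def group_p2p_factor(self, group: int) -> float:
        """ON-phase amplitude factor for site group 1..4."""
        s = GROUP_EFFECT_SCALE[group - 1]
        return 1.0 - s * (1.0 - self.on_p2p_factor)

    def group_rate_factor(self, group: int) -> float:
        s = GROUP_EFFECT_SCALE[group - 1]
        return 1.0 + s * (self.on_rate_factor - 1.0)


@dataclass(frozen=True)
class BackgroundParams:
    """Amplitudes (µV) of the background components."""

    pink_rms_uv: float = 20.0
    line_amp_uv: float = 10.0
    line_hz: float = 50.0
    gamma_rms_uv: float = 6.0
    nominal_p2p_uv: float = 1000.0
    #: Mean injected amplitude scale per site group (distance attenuation).
    group_amp_profile: tuple[float, float, float, float] = (1.0, 0.9, 0.8, 0.7)


@dataclass
class Recording:
    """Multichannel surface recording with optional ground truth.

    ``ground_truth`` rows are (channel, center_time_s, type, injected_p2p_uV).
    """

    signal: np.ndarray  # channels x samples, µV
    fs: float
    channel_groups: dict[int, int]  # channel -> group 1..4
    bad_channel_mask: np.ndarray  # boolean per channel
    ground_truth: list[tuple[int, float, int, float]] | None = None
    protocol: ProtocolTimeline | None = None

    def __post_init__(self):
        if self.fs <= 600:
            raise ValueError(f"fs must be > 600 Hz, got {self.fs!r}")
        n_ch = self.signal.shape[0]
        usable = set(np.flatnonzero(~np.asarray(self.bad_channel_mask)))
        if not usable.issubset(self.channel_groups.keys()) and usable:
            missing = usable - set(self.channel_groups)
            raise ValueError(f"group map does not cover usable channels {sorted(missing)}")
        if len(self.bad_channel_mask) != n_ch:
            raise ValueError("bad_channel_mask length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs

    def channels_in_group(self, group: int) -> list[int]:
        return sorted(c for c, g in self.channel_groups.items() if g == group)


def default_layout(n_channels: int = 32) -> np.ndarray:
    """Distance (mm) of each recording site from the central aperture.

    Sites are laid out in concentric rings of four around the aperture,
    matching a 32-site surface array with a central insertion hole.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels")
    ring = np.arange(n_channels) // 4
    return 0.4 + 0.3 * ring.astype(float)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = 1.0 / np.sqrt(f[nz])
    spec *= scale
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _band_noise(n: int, fs: float, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _event_times(
    rng: np.random.Generator,
    protocol: ProtocolTimeline,
    duration_s: float,
    rate_of: "callable",
) -> list[float]:
    """Hard-core renewal process with phase-dependent rate.

    Gaps are ``min_spacing + Exp(mean = 1/rate - min_spacing)`` so the
    long-run rate matches the configured rate despite the exclusion zone.
    """
    times: list[float] = []
    t = _EDGE_MARGIN_S
    first = True
    while True:
        lam = rate_of(min(t, duration_s - 1e-9))
        if lam <= 0:
            # jump to the next phase boundary where the rate may change
            nxt = next(
                (p.start_s for p in protocol.phases if p.start_s > t), duration_s
            )
            if nxt >= duration_s:
                break
            t = nxt
            continue
        mean_gap = 1.0 / lam
        exp_mean = max(mean_gap - _MIN_SPACING_S, 1e-6)
        if first:
            # stationary start: uniform fraction of a typical gap
            gap = rng.uniform(0, _MIN_SPACING_S) + rng.exponential(exp_mean)
            first = False
        else:
            gap = _MIN_SPACING_S + rng.exponential(exp_mean)
        t += gap
        if t >= duration_s - _EDGE_MARGIN_S:
            break
        times.append(t)
    return times


def simulate_recording(
    protocol: ProtocolTimeline,
    effect_model: EffectModel | None = None,
    n_channels: int = 16,
    fs: float = 2000.0,
    seed: int = 0,
    background: BackgroundParams | None = None,
    layout_mm: np.ndarray | None = None,
    dtype=np.float64,
) -> Recording:
    """Simulate a full multichannel recording with ground-truth events.

    Background per channel: 1/f noise + line hum + a gamma-band (28-80 Hz)
    component whose power is multiplied by ``gamma_boost`` during laser ON;
    an 80-120 Hz narrowband artifact is added while the laser is ON.
    Discharges are injected from a phase-modulated hard-core renewal process;
    injected amplitude is the group nominal times the group's ON factor,
    with no per-event jitter so phase amplitude ratios are exact by
    construction.
    """
    from .preprocessing import group_channels  # local import to avoid cycle

    if fs < 600:
        raise ValueError(f"fs must be >= 600 Hz, got {fs!r}")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    em = effect_model or EffectModel()
    bg = background or BackgroundParams()
    if layout_mm is None:
        layout_mm = default_layout(max(n_channels, 4))[:n_channels]
    mask = np.zeros(n_channels, dtype=bool)
    groups = group_channels(layout_mm, mask) if n_channels >= 4 else {c: 1 for c in range(n_channels)}

    n = int(round(protocol.duration_s * fs))
    t = np.arange(n) / fs
    on_mask = protocol.on_mask(t)
    rng = np.random.default_rng(seed)

    sig = np.empty((n_channels, n), dtype=dtype)
    ground_truth: list[tuple[int, float, int, float]] = []

    # prototype waveforms at unit p2p, reused for every event
    protos = {k: synth_ied(k, 1.0, fs) for k in (1, 2)}
    half = len(protos[1]) // 2

    for ch in range(n_channels):
        g = groups.get(ch, 4)
        x = bg.pink_rms_uv * _pink_noise(n, rng)
        phase0 = rng.uniform(0, 2 * np.pi)
        x += bg.line_amp_uv * np.sin(2 * np.pi * bg.line_hz * t + phase0)
        if bg.gamma_rms_uv > 0:
            gam = bg.gamma_rms_uv * _band_noise(n, fs, 28.0, 80.0, rng)
            boost = np.where(on_mask, np.sqrt(em.gamma_boost), 1.0)
            x += gam * boost
        if em.artifact_amp > 0:
            art = em.artifact_amp * _band_noise(n, fs, 80.0, 120.0, rng)
            x += art * on_mask

        if em.base_rate_hz > 0:
            rate_fac = em.group_rate_factor(g)
            on_starts = np.array([p.start_s for p in protocol.on_phases()])
            on_ends = np.array([p.end_s for p in protocol.on_phases()])

            def rate_of(tt: float) -> float:
                during_on = bool(np.any((tt >= on_starts) & (tt < on_ends)))
                return em.base_rate_hz * (rate_fac if during_on else 1.0)

            for tc in _event_times(rng, protocol, protocol.duration_s, rate_of):
                during_on = bool(protocol.on_mask(np.array([tc]))[0])
                amp = bg.nominal_p2p_uv * bg.group_amp_profile[g - 1]
                if during_on:
                    amp *= em.group_p2p_factor(g)
                typ = 2 if rng.random() < em.type2_fraction else 1
                ci = int(round(tc * fs))
                lo = ci - half
                hi = lo + len(protos[typ])
                if lo < 0 or hi > n:
                    continue
                x[lo:hi] += amp * protos[typ]
                ground_truth.append((ch, tc, typ, amp))

        sig[ch] = x

    return Recording(
        signal=sig,
        fs=float(fs),
        channel_groups=groups,
        bad_channel_mask=mask,
        ground_truth=ground_truth,
        protocol=protocol,
    )
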