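"""Per-discharge features, 40-s binning, and thermal phase segmentation.

Five features are computed from each detected discharge's 300-ms segment of
the 2-300 Hz signal: peak-to-peak amplitude, negative-peak fraction, two
band-power fractions (2-8 Hz and 28-80 Hz relative to 2-300 Hz), and the
discharge rate as the event count per 40-s bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic import ProtocolTimeline, TemperatureTrace, P2ON, P4ON

__all__ = [
    "IedFeatures",
    "BinnedSeries",
    "ThermalPhases",
    "p2p",
    "negative_ratio",
    "band_power_ratio",
    "compute_features",
    "ied_rate",
    "bin_feature",
    "segment_thermal_phases",
    "BIN_S",
    "TOTAL_BAND_HZ",
]

BIN_S = 40.0
TOTAL_BAND_HZ = (2.0, 300.0)
DELTA_THETA_HZ = (2.0, 8.0)
GAMMA_HZ = (28.0, 80.0)

#: Sentinel for features that are undefined on a degenerate segment.
UNDEFINED = float("nan")


@dataclass(frozen=True)
class IedFeatures:
    p2p_uv: float
    n_over_p2p: float
    bp_2_8: float
    bp_28_80: float


@dataclass
class BinnedSeries:
    """Values over contiguous 40-s bins aligned to protocol start."""

    bin_edges_s: np.ndarray  # length n_bins + 1
    values: np.ndarray

    def __post_init__(self):
        widths = np.diff(self.bin_edges_s)
        if not np.allclose(widths, BIN_S):
            raise ValueError("bins must be 40 s wide")
        if len(self.values) != len(self.bin_edges_s) - 1:
            raise ValueError("values length must match bin count")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def bin_index(self, t_s: float) -> int:
        return int(t_s // BIN_S)


@dataclass(frozen=True)
class ThermalPhases:
    heating_up: tuple[float, float] | None
    steady_max: tuple[float, float] | None
    thermal_drop: tuple[float, float] | None
    defined: bool = True


def p2p(segment: np.ndarray) -> float:
    """Peak-to-peak amplitude: max minus min."""
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise ValueError("empty segment")
    return float(x.max() - x.min())


def negative_ratio(segment: np.ndarray) -> float:
    """|negative peak| / peak-to-peak, after centering the segment on its mean.

    Returns NaN for a constant segment (undefined feature).
    """
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise ValueError("empty segment")
    c = x - x.mean()
    span = c.max() - c.min()
    if span == 0:
        return UNDEFINED
    return float(abs(c.min()) / span)


def band_power_ratio(segment: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Fraction of 2-300 Hz spectral power falling in ``band``.

    Single Hann-tapered periodogram of the whole segment (a Welch split would
    destroy the 2-8 Hz resolution of a 300-ms segment); band edges half-open
    [low, high). Returns NaN if total-band power is zero.
    """
    if fs < 600:
        raise ValueError(f"fs must be >= 600 Hz, got {fs!r}")
    lo, hi = band
    if lo < TOTAL_BAND_HZ[0] or hi > TOTAL_BAND_HZ[1]:
        raise ValueError(f"band {band} must lie within {TOTAL_BAND_HZ}")
    f, pxx = sps.periodogram(np.asarray(segment, dtype=float), fs=fs, window="hann")
    total = pxx[(f >= TOTAL_BAND_HZ[0]) & (f < TOTAL_BAND_HZ[1])].sum()
    if total == 0:
        return UNDEFINED
    sub = pxx[(f >= lo) & (f < hi)].sum()
    return float(sub / total)


def compute_features(segment: np.ndarray, fs: float) -> IedFeatures:
    return IedFeatures(
        p2p_uv=p2p(segment),
        n_over_p2p=negative_ratio(segment),
        bp_2_8=band_power_ratio(segment, fs, DELTA_THETA_HZ),
        bp_28_80=band_power_ratio(segment, fs, GAMMA_HZ),
    )


def _protocol_edges(protocol: ProtocolTimeline) -> np.ndarray:
    n_bins = int(math.ceil(protocol.duration_s / BIN_S - 1e-9))
    edges = np.arange(n_bins + 1) * BIN_S
    if not math.isclose(edges[-1], protocol.duration_s):
        raise ValueError(
            f"protocol duration {protocol.duration_s} s is not a multiple of {BIN_S} s bins"
        )
    return edges


def ied_rate(event_times_s, protocol: ProtocolTimeline) -> BinnedSeries:
    """Event count per 40-s bin, bins aligned to t = 0."""
    edges = _protocol_edges(protocol)
    t = np.asarray(
        [getattr(e, "center_time_s", e) for e in event_times_s], dtype=float
    )
    if t.size and (t.min() < 0 or t.max() >= protocol.duration_s):
        raise ValueError("event times outside protocol duration")
    counts, _ = np.histogram(t, bins=edges)
    return BinnedSeries(edges, counts.astype(float))


def bin_feature(event_times_s, feature_values, protocol: ProtocolTimeline) -> BinnedSeries:
    """Per-bin mean of a per-event feature.

    Bins without events are filled by linear interpolation between the
    nearest non-empty bins (edge bins take the nearest non-empty value).
    Raises if every bin is empty.
    """
    edges = _protocol_edges(protocol)
    t = np.asarray([getattr(e, "center_time_s", e) for e in event_times_s], dtype=float)
    v = np.asarray(feature_values, dtype=float)
    if t.shape != v.shape:
        raise ValueError("event times and feature values must have equal length")
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    idx = np.floor(t / BIN_S).astype(int)
    finite = np.isfinite(v)
    np.add.at(sums, idx[finite], v[finite])
    np.add.at(counts, idx[finite], 1)
    vals = np.full(n_bins, np.nan)
    nz = counts > 0
    vals[nz] = sums[nz] / counts[nz]
    if not nz.any():
        raise ValueError("no analyzable events: every bin is empty")
    centers = (edges[:-1] + edges[1:]) / 2
    vals = np.interp(centers, centers[nz], vals[nz])
    return BinnedSeries(edges, vals)


def segment_thermal_phases(
    trace: TemperatureTrace,
    protocol: ProtocolTimeline,
    which: str = "near",
    level_fraction: float = 0.9,
    min_rise_c: float = 0.1,
) -> list[ThermalPhases]:
    """Split each ON/OFF cycle into heating-up / steady-max / thermal-drop.

    Heating-up runs from ON onset to the first crossing of
    ``baseline + level_fraction * (cycle max - baseline)``; steady-max lasts
    until the temperature first drops below that level after OFF onset;
    thermal-drop covers the rest of the cycle. Cycles whose peak rise is
    below ``min_rise_c`` are flagged undefined.
    """
    temp = trace.temp_near_c if which == "near" else trace.temp_far_c
    times = trace.times_s
    out: list[ThermalPhases] = []
    for trial in range(protocol.n_trials):
        on, off = protocol.trial_cycle(trial)
        cyc = (times >= on.start_s) & (times <= off.end_s)
        t_c, x_c = times[cyc], temp[cyc]
        baseline = float(np.interp(on.start_s, times, temp))
        cmax = float(x_c.max())
        if cmax - baseline < min_rise_c:
            out.append(ThermalPhases(None, None, None, defined=False))
            continue
        level = baseline + level_fraction * (cmax - baseline)
        above = x_c >= level
        heat_end_candidates = t_c[above]
        t_heat_end = float(heat_end_candidates[0])
        after_off = (t_c >= off.start_s) & (x_c < level)
        t_steady_end = float(t_c[after_off][0]) if after_off.any() else off.end_s
        out.append(
            ThermalPhases(
                heating_up=(on.start_s, t_heat_end),
                steady_max=(t_heat_end, t_steady_end),
                thermal_drop=(t_steady_end, off.end_s),
            )
        )
    return out
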