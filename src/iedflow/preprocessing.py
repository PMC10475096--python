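"""Filter chain and channel organization for wideband multichannel signals.

The chain is: 50 Hz notch, 2-300 Hz Butterworth band-pass, 80-120 Hz
Butterworth band-stop, applied in that order. Filters run forward-backward
(zero phase) by default, which doubles the effective order per design pass;
a causal mode is available via :class:`FilterConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["FilterConfig", "preprocess_wideband", "group_channels"]


@dataclass(frozen=True)
class FilterConfig:
    notch_hz: float = 50.0
    notch_order: int = 2
    notch_q: float = 30.0
    bandpass_hz: tuple[float, float] = (2.0, 300.0)
    bandpass_order: int = 2
    bandstop_hz: tuple[float, float] = (80.0, 120.0)
    bandstop_order: int = 2
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        edges = (self.notch_hz, *self.bandpass_hz, *self.bandstop_hz)
        if any(e >= nyq for e in edges):
            raise ValueError(f"filter edge >= Nyquist ({nyq} Hz) for fs={fs}")
        if self.bandpass_hz[0] >= self.bandpass_hz[1]:
            raise ValueError("bandpass low edge must be below high edge")
        if self.bandstop_hz[0] >= self.bandstop_hz[1]:
            raise ValueError("bandstop low edge must be below high edge")


def _sos_chain(config: FilterConfig, fs: float) -> list[np.ndarray]:
    b, a = sps.iirnotch(config.notch_hz, config.notch_q, fs=fs)
    notch_sos = sps.tf2sos(b, a)
    bp_sos = sps.butter(config.bandpass_order, config.bandpass_hz, btype="bandpass", fs=fs, output="sos")
    bs_sos = sps.butter(config.bandstop_order, config.bandstop_hz, btype="bandstop", fs=fs, output="sos")
    return [notch_sos, bp_sos, bs_sos]


def preprocess_wideband(
    signal: np.ndarray, fs: float, filter_config: FilterConfig | None = None
) -> np.ndarray:
    """Apply notch, band-pass and band-stop filters along the last axis."""
    config = filter_config or FilterConfig()
    config.validate(fs)
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    apply = sps.sosfiltfilt if config.zero_phase else sps.sosfilt
    for sos in _sos_chain(config, fs):
        x = apply(sos, x, axis=-1)
    return x


def group_channels(layout, bad_channel_mask) -> dict[int, int]:
    """Assign usable channels to four groups by distance from the aperture.

    ``layout`` is a per-channel distance (or rank). Group #1 holds the four
    nearest usable sites; the remainder is split into three near-equal groups
    of increasing distance. Ties are broken by channel index, masked channels
    are excluded from every group.
    """
    dist = np.asarray(layout, dtype=float)
    mask = np.asarray(bad_channel_mask, dtype=bool)
    if dist.ndim != 1 or dist.shape != mask.shape:
        raise ValueError("layout and bad_channel_mask must be 1-D with equal length")
    usable = np.flatnonzero(~mask)
    if len(usable) < 4:
        raise ValueError(f"need at least 4 usable channels, got {len(usable)}")
    order = usable[np.lexsort((usable, dist[usable]))]
    groups: dict[int, int] = {int(c): 1 for c in order[:4]}
    rest = order[4:]
    for gi, chunk in enumerate(np.array_split(rest, 3), start=2):
        for c in chunk:
            groups[int(c)] = gi
    return groups
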