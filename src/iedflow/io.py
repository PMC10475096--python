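"""Recording containers (HDF5 with NPZ fallback) and CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Phase, ProtocolTimeline, Recording

__all__ = [
    "save_recording",
    "load_recording",
    "ground_truth_to_csv",
    "events_to_frame",
    "features_to_frame",
]


def _protocol_to_json(protocol: ProtocolTimeline | None) -> str:
    if protocol is None:
        return ""
    return json.dumps(
        {
            "isp_id": protocol.isp_id,
            "pulse_frequency_hz": protocol.pulse_frequency_hz,
            "n_trials": protocol.n_trials,
            "duty_cycle": protocol.duty_cycle,
            "phases": [[p.label, p.start_s, p.end_s] for p in protocol.phases],
        }
    )


def _protocol_from_json(s: str) -> ProtocolTimeline | None:
    if not s:
        return None
    d = json.loads(s)
    return ProtocolTimeline(
        isp_id=d["isp_id"],
        pulse_frequency_hz=d["pulse_frequency_hz"],
        n_trials=d["n_trials"],
        phases=tuple(Phase(*p) for p in d["phases"]),
        duty_cycle=d["duty_cycle"],
    )


def _gt_array(recording: Recording) -> np.ndarray:
    gt = recording.ground_truth or []
    return np.array(
        [(c, t, ty, a) for c, t, ty, a in gt],
        dtype=[("channel", "i4"), ("t_center_s", "f8"), ("type", "i4"), ("p2p_uV", "f8")],
    )


def save_recording(path: str | Path, recording: Recording) -> Path:
    """Write to ``.h5``/``.hdf5`` via h5py, or ``.npz`` as a fallback."""
    path = Path(path)
    channels = sorted(recording.channel_groups)
    groups = np.array([recording.channel_groups[c] for c in channels], dtype=np.int32)
    gt = _gt_array(recording)
    proto = _protocol_to_json(recording.protocol)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=recording.signal)
            f.create_dataset("fs", data=recording.fs)
            f.create_dataset("group_channels", data=np.array(channels, dtype=np.int32))
            f.create_dataset("groups", data=groups)
            f.create_dataset("bad_channel_mask", data=recording.bad_channel_mask)
            f.create_dataset("ground_truth", data=gt)
            f.attrs["protocol"] = proto
    elif path.suffix == ".npz":
        np.savez(
            path,
            signal=recording.signal,
            fs=recording.fs,
            group_channels=np.array(channels, dtype=np.int32),
            groups=groups,
            bad_channel_mask=recording.bad_channel_mask,
            ground_truth=gt,
            protocol=np.array(proto),
        )
    else:
        raise ValueError(f"unsupported recording format {path.suffix!r}")
    return path


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            signal = f["signal"][...]
            fs = float(f["fs"][()])
            channels = f["group_channels"][...]
            groups = f["groups"][...]
            mask = f["bad_channel_mask"][...].astype(bool)
            gt = f["ground_truth"][...]
            proto = _protocol_from_json(f.attrs.get("protocol", ""))
    elif path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as f:
            signal = f["signal"]
            fs = float(f["fs"])
            channels = f["group_channels"]
            groups = f["groups"]
            mask = f["bad_channel_mask"].astype(bool)
            gt = f["ground_truth"]
            proto = _protocol_from_json(str(f["protocol"]))
    else:
        raise ValueError(f"unsupported recording format {path.suffix!r}")
    ground_truth = [
        (int(r["channel"]), float(r["t_center_s"]), int(r["type"]), float(r["p2p_uV"]))
        for r in gt
    ]
    return Recording(
        signal=signal,
        fs=fs,
        channel_groups={int(c): int(g) for c, g in zip(channels, groups)},
        bad_channel_mask=mask,
        ground_truth=ground_truth,
        protocol=proto,
    )


def ground_truth_to_csv(recording: Recording, path: str | Path) -> Path:
    df = pd.DataFrame(
        recording.ground_truth or [], columns=["channel", "t_center_s", "type", "p2p_uV"]
    )
    df.to_csv(path, index=False)
    return Path(path)


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "channel": e.channel,
                "t_center_s": e.center_time_s,
                "window_index": e.source_window_index,
            }
            for e in events
        ],
        columns=["channel", "t_center_s", "window_index"],
    )


def features_to_frame(events, feature_rows) -> pd.DataFrame:
    rows = []
    for e, f in zip(events, feature_rows):
        rows.append(
            {
                "channel": e.channel,
                "t_center_s": e.center_time_s,
                "p2p_uV": f.p2p_uv,
                "n_over_p2p": f.n_over_p2p,
                "bp_2_8": f.bp_2_8,
                "bp_28_80": f.bp_28_80,
            }
        )
    return pd.DataFrame(
        rows, columns=["channel", "t_center_s", "p2p_uV", "n_over_p2p", "bp_2_8", "bp_28_80"]
    )
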