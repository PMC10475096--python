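"""End-to-end orchestration: simulate -> preprocess -> detect -> featurize ->
analyze, producing event/feature tables, normalized trajectories, the
similarity table and trajectory plots from one configuration.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iio
from .detection import DetectorConfig, detect_ieds
from .features import BIN_S, bin_feature, compute_features, ied_rate
from .preprocessing import FilterConfig, preprocess_wideband
from .stats import (
    FeatureArrayX,
    build_feature_array,
    normalize_to_baseline,
    similarity_rho,
)
from .synthetic import (
    BackgroundParams,
    EffectModel,
    ProtocolTimeline,
    ThermalParams,
    build_protocol,
    simulate_recording,
)

__all__ = ["RunConfig", "run_pipeline", "on_phase_suppression"]

FEATURES = ("p2p_uV", "n_over_p2p", "bp_2_8", "bp_28_80", "rate")
_N_CONTROL_BINS = 3


@dataclass
class RunConfig:
    isp_id: str = "ISP1"
    pulse_frequency_hz: float = 0.0
    n_trials: int = 5
    n_rats: int = 6
    n_channels: int = 16
    fs: float = 2000.0
    effect_model: EffectModel = field(default_factory=EffectModel)
    background: BackgroundParams = field(default_factory=BackgroundParams)
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    detector_config: DetectorConfig = field(default_factory=DetectorConfig)
    features: tuple[str, ...] = FEATURES
    groups: tuple[int, ...] = (1, 2, 3, 4)
    outdir: str = "results/run"
    seed: int = 0
    recording_path: str | None = None  # analyze an existing recording instead

    def __post_init__(self):
        if not self.features or not self.groups:
            raise ValueError("analysis grid (features x groups) must be non-empty")
        unknown = set(self.features) - set(FEATURES)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}; choose from {FEATURES}")
        if self.recording_path and not Path(self.recording_path).exists():
            raise ValueError(f"recording_path {self.recording_path!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        kw = {}
        proto = raw.pop("protocol", {})
        kw.update({k: proto[k] for k in ("isp_id", "pulse_frequency_hz", "n_trials") if k in proto})
        cohort = raw.pop("cohort", {})
        kw.update({k: cohort[k] for k in ("n_rats", "n_channels", "fs") if k in cohort})
        for key, cls_ in (
            ("effect_model", EffectModel),
            ("background", BackgroundParams),
            ("filter_config", FilterConfig),
            ("detector_config", DetectorConfig),
        ):
            if key in raw:
                kw[key] = cls_(**{k: _tupled(v) for k, v in raw.pop(key).items()})
        for key in ("features", "groups"):
            if key in raw:
                kw[key] = tuple(raw.pop(key))
        kw.update(raw)
        return cls(**kw)


def _tupled(v):
    return tuple(v) if isinstance(v, list) else v


def _log(fh, **record):
    record["t"] = round(time.time(), 3)
    fh.write(json.dumps(record, sort_keys=True) + "\n")
    fh.flush()


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and condition."""


def _rat_table(config: RunConfig, protocol: ProtocolTimeline, rat: int, seed: int,
               cache_dir: Path, log) -> pd.DataFrame:
    """Detected events + features for one virtual rat (cached as CSV)."""
    cache = cache_dir / f"rat{rat:02d}_features.csv"
    if cache.exists():
        _log(log, stage="detect+featurize", rat=rat, cached=True)
        return pd.read_csv(cache)
    rec = simulate_recording(
        protocol,
        config.effect_model,
        n_channels=config.n_channels,
        fs=config.fs,
        seed=seed,
        background=config.background,
        dtype=np.float32,
    )
    _log(log, stage="simulate", rat=rat, n_events=len(rec.ground_truth))
    rows = []
    for ch in sorted(rec.channel_groups):
        filt = preprocess_wideband(rec.signal[ch], rec.fs, config.filter_config)
        events = detect_ieds(filt, rec.fs, config.detector_config, channel=ch)
        for e in events:
            f = compute_features(e.segment, rec.fs)
            rows.append(
                {
                    "rat": rat,
                    "channel": ch,
                    "group": rec.channel_groups[ch],
                    "t_center_s": e.center_time_s,
                    "window_index": e.source_window_index,
                    "p2p_uV": f.p2p_uv,
                    "n_over_p2p": f.n_over_p2p,
                    "bp_2_8": f.bp_2_8,
                    "bp_28_80": f.bp_28_80,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "rat", "channel", "group", "t_center_s", "window_index",
            "p2p_uV", "n_over_p2p", "bp_2_8", "bp_28_80",
        ],
    )
    df.to_csv(cache, index=False, float_format="%.10g")
    _log(log, stage="detect+featurize", rat=rat, n_detected=len(df))
    # read back so fresh and cache-resumed runs see bit-identical values
    return pd.read_csv(cache)


def _trial_arrays(df: pd.DataFrame, protocol: ProtocolTimeline, feature: str,
                  group: int, rat: int) -> list[FeatureArrayX]:
    sub = df[df["group"] == group]
    if len(sub) == 0:
        raise StageError(f"analyze: no events for group {group} (rat {rat})")
    times = sub["t_center_s"].to_numpy()
    if feature == "rate":
        series = ied_rate(times, protocol)
    else:
        series = bin_feature(times, sub[feature].to_numpy(), protocol)
    out = []
    for trial in range(protocol.n_trials):
        x = build_feature_array(
            series, protocol, trial,
            metadata={"rat": rat, "feature_name": feature, "site_group": group},
        )
        out.append(normalize_to_baseline(x))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a report dict with paths and tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache_dir = outdir / "cache"
    cache_dir.mkdir(exist_ok=True)
    protocol = build_protocol(config.isp_id, config.pulse_frequency_hz, config.n_trials)

    report: dict = {"outdir": str(outdir), "protocol": protocol}
    with open(outdir / "run_log.jsonl", "w") as log:
        _log(log, stage="start", isp=config.isp_id, seed=config.seed,
             n_rats=config.n_rats, n_trials=config.n_trials)

        if config.recording_path:
            rec = iio.load_recording(config.recording_path)
            tables = []
            for ch in sorted(rec.channel_groups):
                filt = preprocess_wideband(rec.signal[ch], rec.fs, config.filter_config)
                events = detect_ieds(filt, rec.fs, config.detector_config, channel=ch)
                feats = [compute_features(e.segment, rec.fs) for e in events]
                t = iio.features_to_frame(events, feats)
                t.insert(0, "rat", 0)
                t.insert(2, "group", rec.channel_groups[ch])
                tables.append(t)
            rat_tables = {0: pd.concat(tables, ignore_index=True)}
        else:
            seeds = np.random.SeedSequence(config.seed).generate_state(config.n_rats)
            rat_tables = {}
            for rat in range(config.n_rats):
                try:
                    rat_tables[rat] = _rat_table(
                        config, protocol, rat, int(seeds[rat]), cache_dir, log
                    )
                except Exception as exc:  # noqa: BLE001
                    raise StageError(f"simulate/detect failed for rat {rat}: {exc}") from exc

        all_events = pd.concat(rat_tables.values(), ignore_index=True)
        all_events.to_csv(outdir / "events.csv", index=False, float_format="%.10g")
        report["events_csv"] = str(outdir / "events.csv")
        report["n_events"] = len(all_events)

        if config.n_trials == 0:
            msg = "baseline-only run (n_trials = 0): no ON/OFF cycles, similarity not computed"
            _log(log, stage="analyze", notice=msg)
            warnings.warn(msg, stacklevel=2)
            report["notice"] = msg
            report["similarity"] = None
            return report

        sim_rows, traj_rows, x_store = [], [], {}
        for feature in config.features:
            for group in config.groups:
                arrays_by_rat = {}
                for rat, df in rat_tables.items():
                    try:
                        arrays_by_rat[rat] = _trial_arrays(df, protocol, feature, group, rat)
                    except (StageError, ValueError) as exc:
                        _log(log, stage="analyze", feature=feature, group=group,
                             rat=rat, skipped=str(exc))
                x_store[(feature, group)] = arrays_by_rat
                stack = np.array(
                    [a.values for arrs in arrays_by_rat.values() for a in arrs]
                )
                if stack.size:
                    mean, sd = stack.mean(axis=0), stack.std(axis=0)
                    for b, (m, s) in enumerate(zip(mean, sd)):
                        traj_rows.append(
                            {"feature": feature, "group": group, "bin": b,
                             "t_start_s": _bin_start(b, protocol), "mean": m, "sd": s}
                        )
                if len(arrays_by_rat) < 2:
                    _log(log, stage="analyze", feature=feature, group=group,
                         notice="fewer than 2 subjects with arrays; similarity skipped")
                    continue
                res = similarity_rho(arrays_by_rat)
                sim_rows.append(
                    {
                        "feature": feature,
                        "pulse_frequency_hz": config.pulse_frequency_hz,
                        "site_group": group,
                        "rho": res.rho,
                        "p_value": res.p_value,
                        "category": res.category,
                        "n_pairs": res.n_pairs,
                    }
                )
                _log(log, stage="analyze", feature=feature, group=group,
                     rho=round(res.rho, 4), p=round(res.p_value, 4))

        sim = pd.DataFrame(
            sim_rows,
            columns=["feature", "pulse_frequency_hz", "site_group", "rho",
                     "p_value", "category", "n_pairs"],
        )
        sim.to_csv(outdir / "similarity.csv", index=False, float_format="%.10g")
        traj = pd.DataFrame(
            traj_rows, columns=["feature", "group", "bin", "t_start_s", "mean", "sd"]
        )
        traj.to_csv(outdir / "trajectories.csv", index=False, float_format="%.10g")
        _plot_trajectories(traj, protocol, outdir)
        report.update(
            {
                "similarity": sim,
                "similarity_csv": str(outdir / "similarity.csv"),
                "trajectories": traj,
                "trajectories_csv": str(outdir / "trajectories.csv"),
                "x_arrays": x_store,
            }
        )
        _log(log, stage="done", n_similarity_rows=len(sim))
    return report


def _bin_start(bin_index: int, protocol: ProtocolTimeline) -> float:
    # bins 0..2 are control; the cycle bins restart at the ON onset of trial 0
    if bin_index < _N_CONTROL_BINS:
        return bin_index * BIN_S
    return 120.0 + (bin_index - _N_CONTROL_BINS) * BIN_S


def on_phase_suppression(report_or_traj, feature: str = "p2p_uV", group: int = 1) -> float:
    """Relative ON-phase reduction (%) of a normalized feature trajectory.

    100 x (1 - mean of the normalized trajectory over ON-phase bins),
    averaged over all rats/trials of the condition.
    """
    if isinstance(report_or_traj, dict):
        arrays_by_rat = report_or_traj["x_arrays"][(feature, group)]
        protocol = report_or_traj["protocol"]
        stack = np.array([a.values for arrs in arrays_by_rat.values() for a in arrs])
        mean = stack.mean(axis=0)
    else:
        raise TypeError("expected a run_pipeline report dict")
    n_on = int(round(protocol.on_s / BIN_S))
    on_bins = mean[_N_CONTROL_BINS : _N_CONTROL_BINS + n_on]
    return float(100.0 * (1.0 - on_bins.mean()))


def _plot_trajectories(traj: pd.DataFrame, protocol: ProtocolTimeline, outdir: Path) -> None:
    if traj.empty:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir = outdir / "plots"
    plot_dir.mkdir(exist_ok=True)
    for (feature, group), sub in traj.groupby(["feature", "group"]):
        fig, ax = plt.subplots(figsize=(7, 3.2))
        x = sub["bin"].to_numpy() * BIN_S
        ax.plot(x, sub["mean"], lw=1.5)
        ax.fill_between(x, sub["mean"] - sub["sd"], sub["mean"] + sub["sd"], alpha=0.25)
        on_start = _N_CONTROL_BINS * BIN_S
        ax.axvline(on_start, color="g", ls="--", lw=0.8)
        ax.axvline(on_start + protocol.on_s, color="g", ls="--", lw=0.8)
        ax.set_xlabel("time in control + first cycle (s)")
        ax.set_ylabel(f"normalized {feature}")
        ax.set_title(f"{feature}, site group {group}")
        fig.tight_layout()
        fig.savefig(plot_dir / f"traj_{feature}_group{group}.png", dpi=110)
        plt.close(fig)
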