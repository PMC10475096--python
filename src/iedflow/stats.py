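"""Normalized per-trial feature arrays and the trial-similarity statistic.

Each trial's binned feature trajectory over the control phase plus one
ON/OFF cycle forms an array X (12 elements for ISP1, 15 for ISP2),
normalized to the last control bin. Similarity across subjects is the mean
of per-subject Pearson correlations against the grand-average trajectory,
with negative correlations truncated to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from .features import BIN_S, BinnedSeries
from .synthetic import ProtocolTimeline

__all__ = [
    "FeatureArrayX",
    "SimilarityResult",
    "build_feature_array",
    "normalize_to_baseline",
    "similarity_rho",
    "categorize_rho",
    "SIGNIFICANCE_ALPHA",
]

SIGNIFICANCE_ALPHA = 0.05
_N_CONTROL_BINS = 3  # 120-s control phase / 40-s bins


@dataclass
class FeatureArrayX:
    """Binned feature trajectory over control + one ON/OFF cycle."""

    values: np.ndarray
    metadata: dict = field(default_factory=dict)
    normalized: bool = False

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SimilarityResult:
    rho: float
    p_value: float
    category: str
    n_pairs: int

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_ALPHA


def build_feature_array(
    binned_series: BinnedSeries,
    protocol: ProtocolTimeline,
    trial_index: int,
    metadata: dict | None = None,
) -> FeatureArrayX:
    """Concatenate the 3 control bins with the bins of one trial's cycle.

    The control bins, recorded once, are shared by every trial of the
    session; ISP1 arrays have 12 elements, ISP2 arrays 15.
    """
    on, off = protocol.trial_cycle(trial_index)
    n_bins = binned_series.n_bins
    cyc_lo = int(round(on.start_s / BIN_S))
    cyc_hi = int(round(off.end_s / BIN_S))
    if cyc_hi > n_bins or _N_CONTROL_BINS > n_bins:
        raise ValueError(
            f"binned series ({n_bins} bins) does not cover control + trial {trial_index}"
        )
    vals = np.concatenate(
        [binned_series.values[:_N_CONTROL_BINS], binned_series.values[cyc_lo:cyc_hi]]
    )
    if np.any(~np.isfinite(vals)):
        raise ValueError(f"trial {trial_index}: incomplete coverage (non-finite bins)")
    md = dict(metadata or {})
    md.setdefault("trial_index", trial_index)
    md.setdefault("isp_id", protocol.isp_id)
    md.setdefault("pulse_frequency_hz", protocol.pulse_frequency_hz)
    return FeatureArrayX(values=vals, metadata=md)


def normalize_to_baseline(x: FeatureArrayX) -> FeatureArrayX:
    """Divide every element by the last control bin; that bin becomes 1.0."""
    baseline = x.values[_N_CONTROL_BINS - 1]
    if baseline == 0 or not np.isfinite(baseline):
        raise ValueError(
            f"cannot normalize trial {x.metadata.get('trial_index')}: "
            f"last control bin is {baseline!r}"
        )
    return FeatureArrayX(values=x.values / baseline, metadata=dict(x.metadata), normalized=True)


def _as_values(arr) -> np.ndarray:
    return np.asarray(getattr(arr, "values", arr), dtype=float)


def similarity_rho(
    arrays_by_rat: dict,
    leave_one_out: bool = False,
    all_trial_pairs: bool = False,
) -> SimilarityResult:
    """Truncated-mean Pearson similarity across subjects.

    For each subject the Pearson correlation between the grand-average array
    (all subjects' trials pooled) and that subject's trial-average array is
    computed; negative correlations are truncated to zero; ``rho`` is the
    mean over subjects and ``p_value`` the mean per-pair two-sided
    correlation-test p. With ``all_trial_pairs`` every single trial array
    (rather than the subject average) forms a pair. ``leave_one_out``
    excludes the subject under comparison from the grand average.
    """
    if len(arrays_by_rat) < 2:
        raise ValueError("need at least 2 subjects")
    per_rat = {r: [_as_values(a) for a in arrs] for r, arrs in arrays_by_rat.items()}
    lengths = {len(a) for arrs in per_rat.values() for a in arrs}
    if len(lengths) != 1:
        raise ValueError(f"arrays have inconsistent lengths {sorted(lengths)}")
    all_arrays = [a for arrs in per_rat.values() for a in arrs]
    grand = np.mean(all_arrays, axis=0)

    rhos, ps = [], []
    for rat in sorted(per_rat, key=str):
        arrs = per_rat[rat]
        if leave_one_out:
            others = [a for r2, a2 in per_rat.items() if r2 != rat for a in a2]
            ref = np.mean(others, axis=0)
        else:
            ref = grand
        sides = [np.mean(arrs, axis=0)] if not all_trial_pairs else arrs
        for side in sides:
            if np.std(side) == 0 or np.std(ref) == 0:
                warnings.warn(
                    f"subject {rat!r}: constant array, pair excluded from similarity",
                    stacklevel=2,
                )
                continue
            r, p = spstats.pearsonr(ref, side)
            rhos.append(max(float(r), 0.0))
            ps.append(float(p))
    if not rhos:
        raise ValueError("all pairs excluded (constant arrays)")
    rho = float(np.mean(rhos))
    p_value = float(np.mean(ps))
    return SimilarityResult(
        rho=rho, p_value=p_value, category=categorize_rho(rho), n_pairs=len(rhos)
    )


def categorize_rho(rho: float) -> str:
    """weak [0, 0.4), moderate [0.4, 0.8), strong [0.8, 1.0]."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho!r}")
    if rho < 0.4:
        return "weak"
    if rho < 0.8:
        return "moderate"
    return "strong"
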