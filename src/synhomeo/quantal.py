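"""Quantal synaptic metrics.

Group quantal content (evoked amplitude divided by the group-mean mini
amplitude), homeostatic-potentiation ratios, and readily-releasable-pool
estimation by back-extrapolating a linear fit to the last cumulative evoked
amplitudes of a high-frequency train to time zero. Release probability is
the first evoked amplitude divided by the intercept; the paired-pulse ratio
is the second divided by the first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CumulativeProfile",
    "RRPEstimate",
    "group_mean_mepsc",
    "quantal_content",
    "php_ratio",
    "cumulative_profile",
    "rrp_from_cumulative",
    "pr_and_ppr",
    "cell_metrics",
]


@dataclass(frozen=True)
class CumulativeProfile:
    """Train-averaged amplitudes, their running sum and stimulus times."""

    amplitudes: np.ndarray  # mean amplitude per stimulus index
    cumulative: np.ndarray
    times: np.ndarray  # seconds, t_1 = 0
    freq: float


@dataclass(frozen=True)
class RRPEstimate:
    """Back-extrapolated cumulative-amplitude line and derived quantities."""

    intercept: float  # signal units at t = 0
    slope: float  # signal units / s (steady-state replenishment rate)
    rrp_quanta: float  # intercept / group mean mini amplitude
    negative_intercept: bool = False


def group_mean_mepsc(values) -> float:
    """Unweighted mean of per-NMJ mean mini amplitudes.

    Each NMJ contributes equally regardless of how many events were
    averaged within it.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("group is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite mini amplitude in group")
    return float(arr.mean())


def quantal_content(epsc_means, group_mepsc: float) -> np.ndarray:
    """Per-NMJ quantal content: evoked amplitude / group mini amplitude.

    Mini and evoked amplitudes come from different NMJs by design, so the
    divisor is a single group-level quantal size.
    """
    if group_mepsc <= 0:
        raise ValueError("group mean mEPSC must be positive")
    return np.asarray(epsc_means, dtype=float) / group_mepsc


def php_ratio(treated_qc, untreated_qc) -> tuple[np.ndarray, float]:
    """Normalise treated quantal contents to the mean untreated control.

    Returns per-NMJ normalised values and their mean. A mean ratio above 1
    indicates homeostatic potentiation of release.
    """
    treated = np.asarray(treated_qc, dtype=float)
    untreated = np.asarray(untreated_qc, dtype=float)
    if treated.size == 0 or untreated.size == 0:
        raise ValueError("both groups must be nonempty")
    baseline = untreated.mean()
    if baseline == 0:
        raise ValueError("untreated mean is zero")
    normalized = treated / baseline
    return normalized, float(normalized.mean())


def cumulative_profile(trains: pd.DataFrame, freq: float = 60.0) -> CumulativeProfile:
    """Average amplitudes across trains per stimulus index and accumulate.

    ``trains`` is long-format with columns train_id, stimulus_index,
    amplitude (one cell). All trains must have the same stimulus count.
    """
    counts = trains.groupby("train_id")["stimulus_index"].count()
    if counts.nunique() != 1:
        raise ValueError("ragged trains: unequal stimulus counts")
    mean_amp = (
        trains.groupby("stimulus_index")["amplitude"].mean().sort_index().to_numpy()
    )
    cum = np.cumsum(mean_amp)
    t = np.arange(len(mean_amp)) / freq
    return CumulativeProfile(amplitudes=mean_amp, cumulative=cum, times=t, freq=freq)


def rrp_from_cumulative(
    profile: CumulativeProfile, group_mepsc: float, last_k: int = 15
) -> RRPEstimate:
    """Estimate the readily releasable pool from cumulative amplitudes.

    An ordinary least-squares line is fit to the last ``last_k`` cumulative
    values against stimulus time and back-extrapolated to t = 0. The
    intercept divided by the group-mean mini amplitude gives the pool size
    in quanta. Negative intercepts are flagged, not clamped.

    Fitting against stimulus index instead of time rescales only the slope;
    the intercept (and hence the pool estimate) is identical.
    """
    if last_k < 2:
        raise ValueError("last_k must be >= 2")
    n = len(profile.cumulative)
    if n < last_k:
        raise ValueError("profile shorter than last_k")
    if group_mepsc <= 0:
        raise ValueError("group mean mEPSC must be positive")
    t = profile.times[n - last_k :]
    c = profile.cumulative[n - last_k :]
    slope, intercept = np.polyfit(t, c, 1)
    neg = intercept < 0
    if neg:
        warnings.warn("negative back-extrapolated intercept", RuntimeWarning, stacklevel=2)
    return RRPEstimate(
        intercept=float(intercept),
        slope=float(slope),
        rrp_quanta=float(intercept / group_mepsc),
        negative_intercept=bool(neg),
    )


def pr_and_ppr(profile: CumulativeProfile, estimate: RRPEstimate) -> tuple[float, float]:
    """Release probability and paired-pulse ratio from a train profile.

    p_r = first amplitude / back-extrapolated intercept;
    PPR = second amplitude / first amplitude.
    """
    a1 = profile.amplitudes[0]
    if estimate.intercept == 0:
        raise ValueError("zero intercept: release probability undefined")
    if a1 == 0:
        raise ValueError("zero first amplitude: PPR undefined")
    p_r = float(a1 / estimate.intercept)
    ppr = float(profile.amplitudes[1] / a1) if len(profile.amplitudes) > 1 else np.nan
    if not 0 <= p_r <= 1:
        warnings.warn(f"release probability {p_r:.3g} outside [0, 1]", RuntimeWarning, stacklevel=2)
    return p_r, ppr


def cell_metrics(
    trains: pd.DataFrame, group_mepsc: float, freq: float = 60.0, last_k: int = 15
) -> pd.DataFrame:
    """Per-cell metrics table from a multi-cell train table.

    Returns one row per cell_id with columns epsc_mean (first-stimulus
    amplitude), qc, intercept, slope, rrp_quanta, p_r, ppr.
    """
    rows = []
    for cell, sub in trains.groupby("cell_id"):
        prof = cumulative_profile(sub, freq=freq)
        est = rrp_from_cumulative(prof, group_mepsc, last_k=last_k)
        p_r, ppr = pr_and_ppr(prof, est)
        epsc = float(prof.amplitudes[0])
        rows.append(
            {
                "cell_id": cell,
                "epsc_mean": epsc,
                "qc": epsc / group_mepsc,
                "intercept": est.intercept,
                "slope": est.slope,
                "rrp_quanta": est.rrp_quanta,
                "p_r": p_r,
                "ppr": ppr,
            }
        )
    return pd.DataFrame(rows)
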