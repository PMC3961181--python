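"""Sliding-window FC and time-dependence of predictive power.

Windowed FC is estimated on sliding windows of varying length (the classic
20 s to 420 s range in 20 s steps); predictive power between simulated and
empirical windowed FC is computed over *every* pair of equal-length
windows, never index-matched, and summarized by mean (headline), sd and
max.  Predictors that are constant in time — SC alone and the analytic SAR
FC — have no windowed structure: their curve point is the whole-session
predictive power, hence an exactly flat window-length curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .core import BoldTrace, ConnectionMask, FCMatrix, compute_fc
from .evaluation import predictive_power

__all__ = [
    "WindowSpec",
    "windowed_fc",
    "windowed_predictive_power",
    "window_length_curve",
    "duration_curve",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window parameters in seconds."""

    length: float
    step: float = 20.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.step <= 0:
            raise ValueError("window length and step must be positive")


def windowed_fc(trace: BoldTrace, spec: WindowSpec) -> list[FCMatrix]:
    """One FC matrix per window start 0, step, 2*step, ... within the trace.

    Each window's series are implicitly re-standardized by the correlation;
    no session-level detrending is applied.
    """
    si = trace.sampling_interval
    n_len = int(round(spec.length / si))
    if n_len < 3:
        raise ValueError(f"window of {spec.length} s is shorter than 3 samples at TR {si}")
    if n_len > trace.n_samples:
        raise ValueError("trace shorter than the requested window")
    n_step = max(1, int(round(spec.step / si)))
    out = []
    for start in range(0, trace.n_samples - n_len + 1, n_step):
        window = BoldTrace(values=trace.values[:, start:start + n_len],
                           sampling_interval=si)
        out.append(compute_fc(window))
    return out


def windowed_predictive_power(sim_windows: Sequence[FCMatrix],
                              emp_windows: Sequence[FCMatrix],
                              mask: ConnectionMask) -> dict[str, float]:
    """Predictive power over every (simulated, empirical) window pair.

    Returns mean (the headline summary), sd and max over the pairwise r
    values.  For constant predictors pass a single-element simulated
    sequence containing the whole-session prediction.
    """
    if not sim_windows or not emp_windows:
        raise ValueError("window sequences must be non-empty")
    rs = np.array([
        predictive_power(s, e, mask)
        for s in sim_windows for e in emp_windows
    ])
    return {"mean": float(rs.mean()), "sd": float(rs.std()),
            "max": float(rs.max()), "n_pairs": int(rs.size)}


def window_length_curve(sim: Union[BoldTrace, FCMatrix], emp: BoldTrace,
                        lengths: Sequence[float], mask: ConnectionMask,
                        step: float = 20.0) -> list[dict[str, float]]:
    """Mean/sd/max windowed predictive power per window length.

    A BoldTrace predictor is windowed alongside the empirical trace and all
    window pairs are compared.  A constant predictor (an FCMatrix, as for SC
    alone or the analytic SAR FC) is compared to the *whole-session*
    empirical FC at every length, which makes its curve exactly flat.
    """
    out = []
    if isinstance(sim, FCMatrix):
        r = predictive_power(sim, compute_fc(emp), mask)
        for length in lengths:
            out.append({"length": float(length), "mean": r, "sd": 0.0, "max": r,
                        "n_pairs": 1})
        return out
    for length in lengths:
        spec = WindowSpec(length=length, step=step)
        summary = windowed_predictive_power(
            windowed_fc(sim, spec), windowed_fc(emp, spec), mask)
        summary["length"] = float(length)
        out.append(summary)
    return out


def duration_curve(sim_runs: Sequence[BoldTrace], emp_fc: FCMatrix,
                   durations: Sequence[float], mask: ConnectionMask) -> list[dict[str, float]]:
    """Predictive power as a function of simulated run duration.

    For each duration d, FC is computed on the first d seconds of each run,
    the per-run FCs are averaged entrywise, and predictive power against
    the empirical FC is reported.
    """
    if not sim_runs:
        raise ValueError("need at least one simulated run")
    durations = list(durations)
    if any(d2 <= d1 for d1, d2 in zip(durations, durations[1:])):
        raise ValueError("durations must be strictly increasing")
    out = []
    for d in durations:
        fcs = []
        for run in sim_runs:
            n = int(round(d / run.sampling_interval))
            if n > run.n_samples:
                raise ValueError(f"duration {d} s exceeds run length")
            fcs.append(compute_fc(BoldTrace(values=run.values[:, :n],
                                            sampling_interval=run.sampling_interval)).values)
        mean_fc = np.mean(fcs, axis=0)
        np.fill_diagonal(mean_fc, 1.0)
        r = predictive_power(FCMatrix(values=mean_fc), emp_fc, mask)
        out.append({"duration": float(d), "r": r})
    return out
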