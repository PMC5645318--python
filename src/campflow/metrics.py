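"""Validation metrics: averaged relative difference, naive forecasters, MASE.

The central error measure per day is the averaged relative difference

    E(t) = sum_{x in S} |n_sim,x,t - n_data,x,t| / N_data,all(t)

over the set S of camps, where N_data,all(t) is the observed total.
E(t) = 0.5 corresponds to 75% of destinations predicted correctly.

Forecast skill is expressed as a Mean Absolute Scaled Error against a
naive extrapolator that consumes a warmup of w observed days:

    MASE = [ (1/T) * sum_{t=0..T} E(t) ] /
           [ (1/(T-w)) * sum_{t=w..T} E_naive(t) ]

with the normalisers taken literally as 1/T and 1/(T-w) over inclusive
sums (an alternative true-mean normalisation with T+1 and T-w+1 is
available behind a flag). MASE < 1 means the simulation beats the naive
model. Three naive models are provided: flat (0th order), slope (1st
order through days 0 and w) and fraction (day-w camp shares applied to
the known total). Per-conflict MASE values aggregate across conflicts by
a weighted mean with weights equal to each conflict's maximum refugee
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

NAIVE_MODELS = ("flat", "slope", "fraction")
DEFAULT_WARMUPS = (7, 30)


@dataclass
class ValidationFrame:
    """Paired simulated and observed per-camp counts over days 0..T.

    ``sim`` and ``data`` are DataFrames indexed by day with one column
    per camp; the camp set is the union of both sources (and optionally
    the scenario), with missing series treated as zero. ``n_data_all``
    defaults to the day-wise sum of the observed columns; ``n_sim_all``
    to the day-wise sum of the simulated columns (the in-camp total).
    """

    sim: pd.DataFrame
    data: pd.DataFrame
    n_data_all: pd.Series = None  # type: ignore[assignment]
    n_sim_all: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        camps = sorted(set(self.sim.columns) | set(self.data.columns))
        index = self.sim.index.union(self.data.index)
        self.sim = self.sim.reindex(index=index, columns=camps).fillna(0.0)
        self.data = self.data.reindex(index=index, columns=camps).fillna(0.0)
        if self.n_data_all is None:
            self.n_data_all = self.data.sum(axis=1)
        else:
            self.n_data_all = pd.Series(self.n_data_all).reindex(index).fillna(0.0)
        if self.n_sim_all is None:
            self.n_sim_all = self.sim.sum(axis=1)
        else:
            self.n_sim_all = pd.Series(self.n_sim_all).reindex(index).fillna(0.0)

    @property
    def camps(self) -> list[str]:
        return list(self.sim.columns)

    @property
    def days(self) -> np.ndarray:
        return self.sim.index.to_numpy()

    def scaled_sim(self) -> pd.DataFrame:
        """Simulated counts after the N_data_all / N_sim_all correction.

        Days with no agents in camps are left unscaled (degenerate ratio).
        """
        ratio = self.n_data_all / self.n_sim_all.replace(0, np.nan)
        return self.sim.mul(ratio.fillna(1.0), axis=0)


def averaged_relative_difference(frame: ValidationFrame, t: int,
                                 scaled: bool = False) -> float:
    """E(t) for one day; NaN flags an undefined day (zero observed total
    but non-zero counts), which callers exclude from averages."""
    sim = frame.scaled_sim() if scaled else frame.sim
    abs_diff = float((sim.loc[t] - frame.data.loc[t]).abs().sum())
    n_all = float(frame.n_data_all.loc[t])
    if n_all == 0:
        return 0.0 if abs_diff == 0 else float("nan")
    return abs_diff / n_all


def error_series(frame: ValidationFrame, scaled: bool = False) -> pd.Series:
    """E(t) for every day of the frame (vectorised), NaN on flagged days."""
    sim = frame.scaled_sim() if scaled else frame.sim
    abs_diff = (sim - frame.data).abs().sum(axis=1)
    n_all = frame.n_data_all
    e = abs_diff / n_all.replace(0, np.nan)
    e[(n_all == 0) & (abs_diff == 0)] = 0.0
    return e.rename("E")


def naive_forecast(model: str, camp_series: pd.DataFrame,
                   total_series: Optional[pd.Series], w: int) -> pd.DataFrame:
    """Naive per-camp predictions for t in [w, T].

    ``camp_series`` holds the observed per-camp counts indexed by day
    (must cover days 0 and w); ``total_series`` (observed totals) is only
    needed by the fraction model. Forecasts are floored at 0.

    flat:     c_x(t) = c_x(w)
    slope:    c_x(t) = c_x(0) + t * (c_x(w) - c_x(0)) / w
    fraction: c_x(t) = [c_x(w) / sum_y c_y(w)] * N_data_all(t)
    """
    if model not in NAIVE_MODELS:
        raise ValueError(f"unknown naive model {model!r}; expected one of {NAIVE_MODELS}")
    horizon = camp_series.index[camp_series.index >= w]
    anchor_w = camp_series.loc[w]
    if model == "flat":
        pred = pd.DataFrame(
            np.tile(anchor_w.to_numpy(), (len(horizon), 1)),
            index=horizon, columns=camp_series.columns)
    elif model == "slope":
        anchor_0 = camp_series.loc[0]
        rate = (anchor_w - anchor_0) / w
        t = horizon.to_numpy()[:, None]
        pred = pd.DataFrame(
            anchor_0.to_numpy()[None, :] + t * rate.to_numpy()[None, :],
            index=horizon, columns=camp_series.columns)
    else:  # fraction
        if total_series is None:
            raise ValueError("fraction model needs the observed total series")
        total_w = float(anchor_w.sum())
        if total_w == 0:
            shares = pd.Series(1.0 / len(camp_series.columns),
                               index=camp_series.columns)
        else:
            shares = anchor_w / total_w
        totals = total_series.reindex(horizon).to_numpy()[:, None]
        pred = pd.DataFrame(totals * shares.to_numpy()[None, :],
                            index=horizon, columns=camp_series.columns)
    return pred.clip(lower=0.0)


def mase(E: pd.Series, E_naive: pd.Series, w: int, T: int,
         true_mean: bool = False) -> float:
    """Mean Absolute Scaled Error from two daily error series.

    ``E`` covers t = 0..T, ``E_naive`` covers t = w..T. Normalisers are
    the literal 1/T and 1/(T-w); with ``true_mean`` the inclusive window
    lengths T+1 and T-w+1 are used instead. NaN (flagged) days are
    excluded from the sums. Zero naive error with non-zero simulation
    error yields +inf.
    """
    if not T > w >= 0:
        raise ValueError("need T > w >= 0")
    num_norm = T + 1 if true_mean else T
    den_norm = T - w + 1 if true_mean else T - w
    num = float(np.nansum(E.loc[0:T].to_numpy())) / num_norm
    den = float(np.nansum(E_naive.loc[w:T].to_numpy())) / den_norm
    if den == 0:
        return 0.0 if num == 0 else float("inf")
    return num / den


def weighted_mase(mase_by_scenario: Mapping[str, float],
                  weights: Mapping[str, float]) -> float:
    """Weighted mean of per-conflict MASE scores, sum(w*m)/sum(w)."""
    if set(mase_by_scenario) != set(weights):
        raise ValueError(
            f"scenario/weight key mismatch: "
            f"{sorted(set(mase_by_scenario) ^ set(weights))}")
    if any(w <= 0 for w in weights.values()):
        raise ValueError("weights must be > 0")
    total = sum(weights.values())
    return sum(weights[k] * mase_by_scenario[k] for k in weights) / total


@dataclass
class ErrorReport:
    """E(t), a naive model's error series, and the resulting MASE score."""

    E: pd.Series
    E_naive: pd.Series
    w: int
    mase: float

    def __post_init__(self) -> None:
        if self.mase < 0:
            raise ValueError("mase must be >= 0")


def evaluate_naive(frame: ValidationFrame, model: str, w: int,
                   scaled: bool = False, true_mean: bool = False) -> ErrorReport:
    """Compare the simulation against one naive model at one warmup.

    The naive forecaster consumes the *observed* series up to day w and
    is evaluated on t in [w, T] with the same error measure as the
    simulation.
    """
    T = int(frame.days.max())
    E = error_series(frame, scaled=scaled)
    pred = naive_forecast(model, frame.data, frame.n_data_all, w)
    naive_frame = ValidationFrame(sim=pred, data=frame.data.loc[w:],
                                  n_data_all=frame.n_data_all.loc[w:])
    E_naive = error_series(naive_frame)
    return ErrorReport(E=E, E_naive=E_naive, w=w,
                       mase=mase(E, E_naive, w, T, true_mean=true_mean))


def frame_from_run(result, registrations: Mapping[str, "RegistrationSeries"],
                   total: Optional["RegistrationSeries"] = None) -> ValidationFrame:
    """Pair a simulation run with observed registration series.

    Observed series are interpolated onto the run's day grid; the camp
    set is the union of run and data camps. ``total``, when given,
    overrides the default observed total (the day-wise sum of camp
    series).
    """
    index = result.camp_counts.index
    days = index.to_numpy()
    data = pd.DataFrame(
        {name: s.interpolate(days) for name, s in registrations.items()},
        index=index)
    n_data_all = None
    if total is not None:
        n_data_all = pd.Series(total.interpolate(days), index=index)
    return ValidationFrame(sim=result.camp_counts.astype(float), data=data,
                           n_data_all=n_data_all)


def run_table(frame: ValidationFrame, scaled_errors: bool = True) -> pd.DataFrame:
    """Per-day output table: raw and scaled simulated counts, observed
    counts, totals, and E(t)."""
    out = pd.DataFrame(index=frame.sim.index)
    out.index.name = "day"
    scaled = frame.scaled_sim()
    for camp in frame.camps:
        out[f"{camp}_sim"] = frame.sim[camp]
        out[f"{camp}_sim_scaled"] = scaled[camp]
        out[f"{camp}_data"] = frame.data[camp]
    out["total_sim"] = frame.n_sim_all
    out["total_data"] = frame.n_data_all
    out["E"] = error_series(frame, scaled=scaled_errors)
    return out.reset_index()


def mase_table(frame: ValidationFrame,
               models: Sequence[str] = NAIVE_MODELS,
               warmups: Sequence[int] = DEFAULT_WARMUPS,
               scaled: bool = False, true_mean: bool = False) -> pd.DataFrame:
    """MASE for every (model, warmup) pair, shaped like a comparison table:
    one row, columns ``{model}_w{w}``."""
    row = {}
    for w in warmups:
        for model in models:
            row[f"{model}_w{w}"] = evaluate_naive(
                frame, model, w, scaled=scaled, true_mean=true_mean).mase
    return pd.DataFrame([row])
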