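"""Degradation kinetics: half-life fits and ratio summaries.

After translation shutoff (cycloheximide or emetine chase) a protein
degraded by a first-order process decays as I(t) = I(0) exp(-k t), so log
intensity is linear in time and the half-life is ln 2 / k.  Band or
fluorescence intensities are assumed already normalized to a loading
control.  The default fit is ordinary least squares on log intensity —
robust for the 3-5 time points a chase typically has; a nonlinear variant
with a plateau term is available for substrates with a stable fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, InsufficientDataError


@dataclass(frozen=True)
class ChaseSeries:
    """One chase time course for one construct (times in minutes)."""

    construct_label: str
    times: Sequence[float]
    intensities: Sequence[float]
    replicate_id: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if len(t) != len(y):
            raise ConfigurationError("times and intensities differ in length")
        if len(t) and (t[0] != 0 or np.any(np.diff(t) <= 0) or np.any(t < 0)):
            raise ConfigurationError(
                "times must be strictly increasing and start at 0"
            )
        if np.any(y <= 0):
            raise ConfigurationError("intensities must be positive")


@dataclass(frozen=True)
class RatioSample:
    """Per-cell log(mCherry/GFP) values for one construct/treatment."""

    construct_label: str
    treatment_label: str
    log_ratios: Sequence[float]

    def __post_init__(self) -> None:
        x = np.asarray(self.log_ratios, dtype=float)
        if len(x) == 0:
            raise InsufficientDataError("ratio sample is empty")
        if not np.all(np.isfinite(x)):
            raise ConfigurationError("log-ratios must be finite")


@dataclass(frozen=True)
class DecayFit:
    """Result of a half-life fit."""

    k: float                 # 1/min; <= 0 means no measurable decay
    half_life: float         # min; +inf when stable
    r_squared: float
    stderr_k: float
    stable: bool
    n_points: int
    model: str = "loglinear"


def fit_decay_halflife(
    series: ChaseSeries, model: str = "loglinear"
) -> DecayFit:
    """Fit first-order decay to a chase series.

    ``loglinear`` (default): least squares of log intensity vs time,
    k = -slope.  ``plateau``: nonlinear fit of c + (I0 - c) exp(-k t) for
    substrates with an undegradable fraction.  A non-positive fitted k is
    reported as stable with infinite half-life rather than an error — flat
    chases are a real observation.
    """
    t = np.asarray(series.times, dtype=float)
    y = np.asarray(series.intensities, dtype=float)
    if len(t) < 3:
        raise InsufficientDataError(
            f"need >= 3 time points, got {len(t)} "
            f"({series.construct_label!r})"
        )
    if model == "loglinear":
        res = stats.linregress(t, np.log(y))
        k = -res.slope
        r2 = res.rvalue ** 2
        stderr = res.stderr
    elif model == "plateau":
        def decay(tt, i0, k_, c):
            return c + (i0 - c) * np.exp(-k_ * tt)
        p0 = (y[0], max(1e-4, -np.polyfit(t, np.log(y), 1)[0]), y.min() / 2)
        popt, pcov = optimize.curve_fit(
            decay, t, y, p0=p0,
            bounds=([0, 0, 0], [np.inf, np.inf, np.inf]), maxfev=10_000,
        )
        k = popt[1]
        resid = y - decay(t, *popt)
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else 1.0
        stderr = float(np.sqrt(pcov[1, 1]))
    else:
        raise ConfigurationError(f"unknown model {model!r}")

    stable = k <= 0
    half_life = math.inf if stable else math.log(2) / k
    return DecayFit(
        k=float(k), half_life=half_life, r_squared=float(r2),
        stderr_k=float(stderr), stable=stable, n_points=len(t), model=model,
    )


def fit_many(series_list: Sequence[ChaseSeries],
             model: str = "loglinear") -> pd.DataFrame:
    """Fit every series; one row per (construct, replicate)."""
    rows = []
    for s in series_list:
        fit = fit_decay_halflife(s, model=model)
        rows.append({
            "construct": s.construct_label,
            "replicate": s.replicate_id,
            "k_per_min": fit.k,
            "half_life_min": fit.half_life,
            "r_squared": fit.r_squared,
            "stderr_k": fit.stderr_k,
            "stable": fit.stable,
        })
    return pd.DataFrame(rows)


def chase_series_from_tidy(df: pd.DataFrame) -> List[ChaseSeries]:
    """Split a tidy table (construct, replicate, time_min, intensity)."""
    required = {"construct", "replicate", "time_min", "intensity"}
    if not required <= set(df.columns):
        raise ConfigurationError(
            f"tidy chase table needs columns {sorted(required)}"
        )
    out = []
    for (construct, rep), grp in df.groupby(["construct", "replicate"]):
        grp = grp.sort_values("time_min")
        out.append(ChaseSeries(
            construct_label=str(construct),
            times=grp["time_min"].to_numpy(),
            intensities=grp["intensity"].to_numpy(),
            replicate_id=int(rep),
        ))
    return out


def mean_ratio_summary(
    samples: Sequence[RatioSample], arithmetic: bool = False
) -> pd.DataFrame:
    """Per-construct mCherry/GFP ratio summary.

    Default is geometric: mean of log-ratios exponentiated, with the SD
    reported on the log scale — flow ratios are log-normal to a good
    approximation.  ``arithmetic=True`` averages raw ratios instead.
    """
    if len(samples) == 0:
        raise InsufficientDataError("no ratio samples given")
    rows = []
    for s in samples:
        x = np.asarray(s.log_ratios, dtype=float)
        if arithmetic:
            r = np.exp(x)
            mean = float(r.mean())
            sd = float(r.std(ddof=1)) if len(r) > 1 else 0.0
        else:
            mean = float(np.exp(x.mean()))
            sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
        rows.append({
            "construct": s.construct_label,
            "treatment": s.treatment_label,
            "mean_ratio": mean,
            "sd": sd,
            "n": len(x),
        })
    return pd.DataFrame(rows)
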