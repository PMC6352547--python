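"""Velocity-bout statistics: synthetic ensembles, averaging, exponential fits.

Real locomotor bouts appear in velocity recordings as a plateau of steady
walking that terminates in a sharp drop to rest, with bout durations that are
approximately exponentially distributed.  The recorded locust dataset behind
those observations is not publicly deposited, so this module ships a
*synthetic* generator that emulates the ensemble's shape — plateau near 1
after normalization, sigmoidal drop at an exponentially distributed time,
additive Gaussian measurement noise — plus the averaging and fitting
utilities used to summarize such ensembles (pointwise mean with 95%
confidence bands, maximum-likelihood exponential duration fits with a
semilog goodness measure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "VelocityTrace",
    "BoutEnsemble",
    "generate_synthetic_bouts",
    "sigmoid_bout",
    "normalize_trace",
    "average_bouts",
    "fit_exponential",
    "read_velocity_csv",
    "write_velocity_csv",
]


@dataclass
class VelocityTrace:
    """One velocity time series aligned to bout onset."""

    t: np.ndarray
    v: np.ndarray
    normalized: bool = False
    drop_center: float | None = None   # generator ground truth, if synthetic

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise ValueError("t and v must have equal length")


@dataclass
class BoutEnsemble:
    """A collection of onset-aligned velocity traces on a common time grid."""

    traces: list[VelocityTrace]
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.traces)

    @property
    def t(self) -> np.ndarray:
        return self.traces[0].t

    def as_matrix(self) -> np.ndarray:
        grids = {tr.t.shape[0] for tr in self.traces}
        if len(grids) != 1 or any(
            not np.array_equal(tr.t, self.t) for tr in self.traces
        ):
            raise ValueError("traces are not on a common time grid")
        return np.stack([tr.v for tr in self.traces])


def sigmoid_bout(t: np.ndarray, plateau: float, center: float, width: float) -> np.ndarray:
    """Noiseless bout template: plateau * logistic drop centered at ``center``."""
    return plateau / (1.0 + np.exp((np.asarray(t, dtype=float) - center) / width))


def normalize_trace(trace: VelocityTrace) -> VelocityTrace:
    """Scale a trace so its onset velocity v(0) equals 1 (idempotent)."""
    v0 = trace.v[0]
    if v0 == 0:
        raise ValueError("cannot normalize a trace with v(0) = 0")
    if trace.normalized:
        return trace
    return VelocityTrace(trace.t, trace.v / v0, normalized=True, drop_center=trace.drop_center)


def generate_synthetic_bouts(
    n: int = 43,
    plateau_level: float = 1.0,
    drop_sharpness: float = 0.1,
    duration_rate: float = 0.5,
    noise_sd: float = 0.03,
    seed: int | None = 0,
    *,
    dt: float = 0.05,
    t_max: float = 20.0,
    min_duration: float = 1.0,
) -> BoutEnsemble:
    """Generate an onset-aligned ensemble of synthetic velocity bouts.

    Each trace is ``plateau_level`` times a logistic drop of width
    ``drop_sharpness`` centered at ``min_duration + Exp(duration_rate)``
    (every bout keeps a minimal plateau before terminating), plus i.i.d.
    Gaussian noise of SD ``noise_sd``, normalized so that v(0) = 1.

    The defaults mimic the published ensemble shape at desk scale: n = 43
    traces, a plateau near 1, sharp terminations, exponential durations with
    mean ``min_duration + 1/duration_rate`` time units.  This is a synthetic
    stand-in shaped like the empirical ensemble, not a reproduction of it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if min(plateau_level, drop_sharpness, duration_rate, dt, t_max) <= 0:
        raise ValueError("all scales must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max + 0.5 * dt, dt)
    traces = []
    for _ in range(n):
        center = min_duration + rng.exponential(1.0 / duration_rate)
        v = sigmoid_bout(t, plateau_level, center, drop_sharpness)
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, t.shape)
        traces.append(
            normalize_trace(VelocityTrace(t, v, normalized=False, drop_center=center))
        )
    return BoutEnsemble(
        traces=traces,
        seed=seed,
        meta={
            "plateau_level": plateau_level,
            "drop_sharpness": drop_sharpness,
            "duration_rate": duration_rate,
            "noise_sd": noise_sd,
            "min_duration": min_duration,
            "synthetic": True,
        },
    )


def average_bouts(ensemble: BoutEnsemble) -> pd.DataFrame:
    """Pointwise ensemble mean with a 95% confidence band (2*SD/sqrt(n)).

    Returns a frame with columns t, mean, ci (half-width), ci_lo, ci_hi.
    Traces must share one time grid.
    """
    V = ensemble.as_matrix()
    n = V.shape[0]
    mean = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    ci = 2.0 * sd / math.sqrt(n)
    return pd.DataFrame(
        {"t": ensemble.t, "mean": mean, "ci": ci, "ci_lo": mean - ci, "ci_hi": mean + ci}
    )


def fit_exponential(durations, *, shift: float | str | None = None, min_n: int = 30) -> dict:
    """Maximum-likelihood exponential fit to bout durations.

    ``shift``: optional location offset subtracted before fitting ("auto"
    uses the sample minimum, for ensembles whose plateau imposes a minimal
    duration).  Returns the ML rate (1 / mean excess) and the R^2 of the
    empirical log-survival function against a straight line — the analogue of
    checking that durations lay out on one slope on a semilog plot.
    """
    d = np.asarray(durations, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < min_n:
        raise ValueError(f"need at least {min_n} durations, got {d.size}")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    if np.ptp(d) == 0:
        raise ValueError("degenerate sample: all durations equal")
    if shift == "auto":
        loc = float(d.min())
        d_fit = d - loc
        d_fit = d_fit[d_fit > 0]
    elif shift:
        loc = float(shift)
        d_fit = d - loc
        if np.any(d_fit < 0):
            raise ValueError("shift exceeds some durations")
        d_fit = d_fit[d_fit > 0]
    else:
        loc = 0.0
        d_fit = d
    rate = 1.0 / float(d_fit.mean())
    srt = np.sort(d_fit)
    surv = 1.0 - np.arange(1, srt.size + 1) / (srt.size + 1.0)
    reg = scipy.stats.linregress(srt, np.log(surv))
    return {
        "rate": rate,
        "loc": loc,
        "n": int(d_fit.size),
        "semilog_r2": float(reg.rvalue**2),
        "semilog_slope": float(reg.slope),
    }


def read_velocity_csv(path) -> VelocityTrace:
    """Read a velocity trace from CSV with columns t, v."""
    df = pd.read_csv(path)
    if not {"t", "v"}.issubset(df.columns):
        raise ValueError("velocity CSV must have columns t, v")
    return VelocityTrace(df["t"].to_numpy(), df["v"].to_numpy())


def write_velocity_csv(trace: VelocityTrace, path) -> None:
    pd.DataFrame({"t": trace.t, "v": trace.v}).to_csv(path, index=False)
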