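"""Stochastic gait simulation: bouts, order parameters, durations, sweeps.

The stochastic model is integrated with the Euler-Maruyama scheme,

    phi(t + dt) = phi(t) + drift(phi) dt + sigma * sqrt(dt) * z,   z ~ N(0, I),

so that results are dt-independent in the white-noise reading of the model's
nu(t) term.  (A legacy per-step reading, where the noise increment is sigma
regardless of dt, is available via ``noise_per_step=True``.)

A locomotive *bout* starts at the exact double-tripod pattern; the white noise
supplies the perturbation that eventually tips the unstable gait into the
stable synchronous (idling) state.  Proximity to the two gaits is measured by
the order parameters

    xi_Idl(t) = |mean_n exp(i phi_n)|,
    xi_Tri(t) = |mean_n (-1)^n exp(i phi_n)|,

both in [0, 1].  A bout's duration is the *last* down-crossing time of xi_Tri
through 0.15 (or, for the half-life, through 0.5); its termination is *sharp*
when xi_Tri falls from 0.85 to 0.15 within a window of 3 * tau6, where
tau6 = -1/(2 Gamma H'(pi)) is the slow divergence timescale, and *irregular*
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .network import N_LEGS, TRIPOD, ModelParams, drift

__all__ = [
    "Trajectory",
    "BoutRecord",
    "SweepResult",
    "integrate",
    "order_parameters",
    "xi_idle",
    "xi_tripod",
    "run_bout",
    "run_bouts",
    "bout_duration",
    "last_down_crossing",
    "classify_transition",
    "sweep_rho",
    "duration_distribution",
    "sweep_tau",
]

DT_DEFAULT = 0.01
T_MAX_DEFAULT = 50.0

#: a bout has terminated once xi_Tri stays below this level ...
TERMINATION_LEVEL = 0.05
#: ... for at least this long (model time units)
TERMINATION_DWELL = 1.0

#: duration thresholds on xi_Tri
LAST_CROSSING_LEVEL = 0.15
HALF_LIFE_LEVEL = 0.5
#: upper threshold of the sharpness rule
SHARP_UPPER_LEVEL = 0.85
#: sharp iff the 0.85 -> 0.15 drop completes within this many tau6
SHARP_WINDOW_TAU6 = 3.0

_SIGNS = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])


# ---------------------------------------------------------------------------
# Order parameters
# ---------------------------------------------------------------------------

def xi_idle(phi: np.ndarray) -> np.ndarray:
    """Synchrony order parameter |mean exp(i phi)| over the last axis."""
    return np.abs(np.exp(1j * np.asarray(phi)).mean(axis=-1))


def xi_tripod(phi: np.ndarray) -> np.ndarray:
    """Double-tripod order parameter |mean (-1)^n exp(i phi)|."""
    return np.abs((_SIGNS * np.exp(1j * np.asarray(phi))).mean(axis=-1))


def order_parameters(traj) -> tuple[np.ndarray, np.ndarray]:
    """(xi_Idl, xi_Tri) series of a trajectory or raw phase array.

    Both are insensitive to 2*pi wraps and to uniform phase shifts.
    """
    phi = traj.phi if hasattr(traj, "phi") else np.asarray(traj)
    return xi_idle(phi), xi_tripod(phi)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """One integrated path: time grid, unwrapped phases, order parameters."""

    t: np.ndarray                 # (steps + 1,)
    phi: np.ndarray               # (steps + 1, 6), unwrapped
    seed: int | None
    params: ModelParams
    dt: float

    xi_idl: np.ndarray = field(init=False)
    xi_tri: np.ndarray = field(init=False)

    def __post_init__(self):
        self.xi_idl = xi_idle(self.phi)
        self.xi_tri = xi_tripod(self.phi)

    def to_frame(self) -> pd.DataFrame:
        """Tidy CSV-ready frame: t, phi1..phi6, xi_idl, xi_tri."""
        cols = {f"phi{i + 1}": self.phi[:, i] for i in range(N_LEGS)}
        return pd.DataFrame({"t": self.t, **cols, "xi_idl": self.xi_idl, "xi_tri": self.xi_tri})


def integrate(
    state0: np.ndarray,
    mp: ModelParams,
    dt: float = DT_DEFAULT,
    t_max: float = T_MAX_DEFAULT,
    seed: int | None = 0,
    *,
    noise_per_step: bool = False,
) -> Trajectory:
    """Integrate the stochastic phase dynamics from ``state0``.

    In noise mode "white" the Euler-Maruyama increment is sigma*sqrt(dt)*z per
    node per step; in mode "initial_kick" the initial state is perturbed once
    by N(0, sigma^2) per node and the integration is deterministic.

    Raises ``FloatingPointError`` with the offending step and node if the
    phases leave the finite range.
    """
    if dt <= 0 or t_max <= dt:
        raise ValueError("require dt > 0 and t_max > dt")
    phi = np.array(state0, dtype=float)
    if phi.shape != (N_LEGS,):
        raise ValueError("state0 must be a 6-vector")
    rng = np.random.default_rng(seed)
    steps = int(round(t_max / dt))
    out = np.empty((steps + 1, N_LEGS))
    if mp.noise_mode == "initial_kick" and mp.sigma > 0:
        phi = phi + rng.normal(0.0, mp.sigma, N_LEGS)
    out[0] = phi
    noise_scale = mp.sigma * (1.0 if noise_per_step else math.sqrt(dt))
    white = mp.noise_mode == "white" and mp.sigma > 0
    for s in range(steps):
        phi = phi + drift(phi, mp) * dt
        if white:
            phi = phi + noise_scale * rng.standard_normal(N_LEGS)
        if not np.all(np.isfinite(phi)):
            bad = int(np.argmax(~np.isfinite(phi)))
            raise FloatingPointError(
                f"non-finite phase at step {s + 1} (t={dt * (s + 1):.4g}), node {bad + 1}"
            )
        out[s + 1] = phi
    t = np.arange(steps + 1) * dt
    return Trajectory(t=t, phi=out, seed=seed, params=mp, dt=dt)


def _integrate_ensemble_xi(
    mp: ModelParams, n: int, dt: float, t_max: float, seed: int, *, noise_per_step: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized double-tripod bout ensemble; returns (t, xi_tri[n, steps+1]).

    All ``n`` realizations start at the exact double-tripod pattern and share
    one seeded noise stream, which keeps ensembles bit-reproducible.
    """
    rng = np.random.default_rng(seed)
    steps = int(round(t_max / dt))
    phi = np.tile(TRIPOD, (n, 1))
    if mp.noise_mode == "initial_kick" and mp.sigma > 0:
        phi = phi + rng.normal(0.0, mp.sigma, (n, N_LEGS))
    xi = np.empty((n, steps + 1))
    xi[:, 0] = xi_tripod(phi)
    noise_scale = mp.sigma * (1.0 if noise_per_step else math.sqrt(dt))
    white = mp.noise_mode == "white" and mp.sigma > 0
    for s in range(steps):
        phi = phi + drift(phi, mp) * dt
        if white:
            phi = phi + noise_scale * rng.standard_normal((n, N_LEGS))
        xi[:, s + 1] = xi_tripod(phi)
    t = np.arange(steps + 1) * dt
    return t, xi


# ---------------------------------------------------------------------------
# Bout durations and classification
# ---------------------------------------------------------------------------

def last_down_crossing(t: np.ndarray, series: np.ndarray, level: float) -> float:
    """Time of the final down-crossing of ``series`` through ``level``.

    Linear interpolation between samples.  Returns ``nan`` if the series never
    sits at/above the level, or never comes back down after its last visit.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(series, dtype=float)
    above = y >= level
    if not above.any():
        return math.nan
    j = int(np.nonzero(above)[0][-1])
    if j == len(y) - 1:
        return math.nan  # still at/above the level at the end of the record
    y0, y1 = y[j], y[j + 1]
    frac = (y0 - level) / (y0 - y1)
    return float(t[j] + frac * (t[j + 1] - t[j]))


def bout_duration(
    t: np.ndarray, xi_tri: np.ndarray, method: str = "last_crossing_015"
) -> float:
    """Bout duration from the tripod order-parameter series.

    ``last_crossing_015``: last down-crossing of 0.15 (the bout's full
    duration); ``half_life_05``: last down-crossing of 0.5.  Returns ``nan``
    when the series never decays through the threshold.
    """
    if method == "last_crossing_015":
        level = LAST_CROSSING_LEVEL
    elif method == "half_life_05":
        level = HALF_LIFE_LEVEL
    else:
        raise ValueError(f"unknown duration method {method!r}")
    xi_tri = np.asarray(xi_tri, dtype=float)
    if xi_tri[0] < level:
        raise ValueError("series must start at or above the threshold")
    return last_down_crossing(t, xi_tri, level)


@dataclass
class BoutRecord:
    """One simulated locomotive bout and its summary measures."""

    duration_last015: float       # last down-crossing of xi_Tri = 0.15 (nan if censored)
    duration_halflife: float      # last down-crossing of xi_Tri = 0.5
    drop_interval: float          # time between last 0.85 and last 0.15 crossings
    label: str                    # "sharp" | "irregular" | "censored"
    terminal_idle: bool           # xi_Tri settled below the termination level
    seed: int | None = None
    trajectory: Trajectory | None = None

    @property
    def decayed(self) -> bool:
        return self.label != "censored"


def _record_from_series(t, xi, tau6, sharp_window, seed=None, trajectory=None) -> BoutRecord:
    dt = t[1] - t[0]
    dwell = max(int(round(TERMINATION_DWELL / dt)), 1)
    tail = xi[-dwell:]
    terminal_idle = bool(np.all(tail < TERMINATION_LEVEL))
    d15 = last_down_crossing(t, xi, LAST_CROSSING_LEVEL)
    d50 = last_down_crossing(t, xi, HALF_LIFE_LEVEL)
    d85 = last_down_crossing(t, xi, SHARP_UPPER_LEVEL)
    if math.isnan(d15) or not terminal_idle:
        label = "censored"
        drop = math.nan
    else:
        drop = d15 - d85 if not math.isnan(d85) else math.nan
        window = sharp_window if sharp_window is not None else SHARP_WINDOW_TAU6 * tau6
        label = "sharp" if (not math.isnan(drop) and drop <= window) else "irregular"
    return BoutRecord(
        duration_last015=d15,
        duration_halflife=d50,
        drop_interval=drop,
        label=label,
        terminal_idle=terminal_idle,
        seed=seed,
        trajectory=trajectory,
    )


def run_bout(
    mp: ModelParams,
    dt: float = DT_DEFAULT,
    t_max: float = T_MAX_DEFAULT,
    seed: int | None = 0,
    *,
    sharp_window: float | None = None,
    keep_trajectory: bool = True,
) -> BoutRecord:
    """Simulate one locomotive bout from the exact double-tripod pattern."""
    traj = integrate(TRIPOD, mp, dt=dt, t_max=t_max, seed=seed)
    return _record_from_series(
        traj.t, traj.xi_tri, mp.tau6, sharp_window, seed=seed,
        trajectory=traj if keep_trajectory else None,
    )


def run_bouts(
    mp: ModelParams,
    n: int,
    dt: float = DT_DEFAULT,
    t_max: float = T_MAX_DEFAULT,
    seed: int = 0,
    *,
    sharp_window: float | None = None,
) -> list[BoutRecord]:
    """Simulate an ensemble of ``n`` bouts (vectorized; one seeded stream)."""
    t, xi = _integrate_ensemble_xi(mp, n, dt, t_max, seed)
    return [_record_from_series(t, xi[i], mp.tau6, sharp_window, seed=seed) for i in range(n)]


def classify_transition(rec: BoutRecord, sharp_window: float) -> str:
    """Re-label a decayed bout as sharp/irregular for a given drop window."""
    if not rec.decayed:
        raise ValueError("censored bouts cannot be classified")
    if math.isnan(rec.drop_interval):
        return "irregular"
    return "sharp" if rec.drop_interval <= sharp_window else "irregular"


def _fraction_sharp(records: Iterable[BoutRecord]) -> tuple[float, int, int]:
    records = list(records)
    decayed = [r for r in records if r.decayed]
    n_sharp = sum(r.label == "sharp" for r in decayed)
    rho = n_sharp / len(decayed) if decayed else math.nan
    return rho, len(decayed), len(records) - len(decayed)


# ---------------------------------------------------------------------------
# Ensemble sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Aggregated bout statistics over a parameter grid."""

    axis: str                       # swept parameter name
    grid: np.ndarray
    table: pd.DataFrame             # one row per grid point
    records: list[list[BoutRecord]]
    seeds: list[int]
    fit: dict = field(default_factory=dict)


def sweep_rho(
    k_grid: Sequence[float],
    mp: ModelParams,
    n: int = 200,
    dt: float = DT_DEFAULT,
    t_max: float = T_MAX_DEFAULT,
    seed: int = 0,
) -> SweepResult:
    """Fraction of sharp transitions rho as a function of feedback strength k."""
    if n < 30:
        raise ValueError("need n >= 30 bouts per grid point for a stable fraction")
    rows, all_records, seeds = [], [], []
    for i, k in enumerate(k_grid):
        point_seed = seed + i
        recs = run_bouts(mp.with_(k=float(k)), n, dt=dt, t_max=t_max, seed=point_seed)
        rho, n_dec, n_cens = _fraction_sharp(recs)
        rows.append({"k": float(k), "rho": rho, "n_decayed": n_dec, "n_censored": n_cens})
        all_records.append(recs)
        seeds.append(point_seed)
    return SweepResult(
        axis="k",
        grid=np.asarray(k_grid, dtype=float),
        table=pd.DataFrame(rows),
        records=all_records,
        seeds=seeds,
    )


def duration_distribution(
    records: Sequence[BoutRecord] | np.ndarray,
    bins: int = 30,
    *,
    method: str = "last_crossing_015",
) -> dict:
    """Normalized duration histogram P(T) with an exponential tail fit.

    The tail fit is a maximum-likelihood exponential to the durations beyond
    the histogram mode (rate = 1 / mean excess); goodness is the R^2 of the
    empirical log-survival of the tail against a straight line.
    """
    if len(records) and isinstance(records[0], BoutRecord):
        attr = "duration_last015" if method == "last_crossing_015" else "duration_halflife"
        durations = np.array([getattr(r, attr) for r in records if r.decayed])
    else:
        durations = np.asarray(records, dtype=float)
    durations = durations[np.isfinite(durations)]
    if durations.size < 100:
        return {"durations": durations, "fit_declined": f"need >= 100 decayed bouts, got {durations.size}"}
    density, edges = np.histogram(durations, bins=bins, density=True)
    mode = 0.5 * (edges[np.argmax(density)] + edges[np.argmax(density) + 1])
    tail = durations[durations > mode]
    rate = 1.0 / np.mean(tail - mode)
    srt = np.sort(tail)
    surv = 1.0 - np.arange(1, srt.size + 1) / (srt.size + 1.0)
    reg = scipy.stats.linregress(srt, np.log(surv))
    return {
        "durations": durations,
        "density": density,
        "edges": edges,
        "mode": mode,
        "tail_rate": float(rate),
        "tail_n": int(tail.size),
        "semilog_r2": float(reg.rvalue**2),
        "semilog_slope": float(reg.slope),
    }


def sweep_tau(
    axis: str,
    grid: Sequence[float],
    mp: ModelParams,
    n: int = 50,
    dt: float = DT_DEFAULT,
    t_max: float = T_MAX_DEFAULT,
    seed: int = 0,
) -> SweepResult:
    """Mean bout half-life <tau> versus coupling strength Gamma or noise sigma.

    95% confidence half-widths are 2 * SD / sqrt(n).  For ``axis="gamma"`` the
    fit is a power law (slope of log<tau> vs log Gamma, prediction -1); for
    ``axis="sigma"`` it is <tau> = a + b * ln(sigma) (logarithmic decline).
    """
    if axis not in ("gamma", "sigma"):
        raise ValueError("axis must be 'gamma' or 'sigma'")
    if n < 30:
        raise ValueError("need n >= 30 bouts per grid point")
    rows, all_records, seeds = [], [], []
    for i, val in enumerate(grid):
        point_seed = seed + i
        recs = run_bouts(mp.with_(**{axis: float(val)}), n, dt=dt, t_max=t_max, seed=point_seed)
        hl = np.array([r.duration_halflife for r in recs if r.decayed and np.isfinite(r.duration_halflife)])
        n_cens = sum(not r.decayed for r in recs)
        rows.append({
            axis: float(val),
            "tau_mean": float(hl.mean()) if hl.size else math.nan,
            "tau_ci": float(2.0 * hl.std(ddof=1) / math.sqrt(hl.size)) if hl.size > 1 else math.nan,
            "n_decayed": int(hl.size),
            "n_censored": n_cens,
            "censored_dominated": n_cens > len(recs) / 2,
        })
        all_records.append(recs)
        seeds.append(point_seed)
    table = pd.DataFrame(rows)
    ok = table["tau_mean"].notna()
    fit: dict = {}
    if ok.sum() >= 2:
        x = table.loc[ok, axis].to_numpy()
        y = table.loc[ok, "tau_mean"].to_numpy()
        if axis == "gamma":
            reg = scipy.stats.linregress(np.log(x), np.log(y))
            fit = {"kind": "power_law", "slope": float(reg.slope), "r2": float(reg.rvalue**2)}
        else:
            reg = scipy.stats.linregress(np.log(x), y)
            fit = {"kind": "logarithmic", "slope": float(reg.slope), "r2": float(reg.rvalue**2)}
    return SweepResult(
        axis=axis, grid=np.asarray(grid, dtype=float), table=table,
        records=all_records, seeds=seeds, fit=fit,
    )
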