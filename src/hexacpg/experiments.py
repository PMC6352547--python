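"""Preset experiments: fixed points, spectra, bouts, and ensemble sweeps.

Each experiment mirrors one of the model's simulation protocols — single
bouts with and without feedback, the sharp-fraction sweep rho(k), bout
duration distributions P(T), and the lifetime sweeps <tau>(Gamma) and
<tau>(sigma) — at an ensemble scale small enough for a single CPU.  Results
are written as CSV/JSON together with a manifest capturing the fully
resolved configuration and seeds, sufficient for bit-exact re-runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import boutstats, simulate, theory
from .network import (
    IDLE,
    TRIPOD,
    ConnectivityParams,
    ModelParams,
    build_connectivity,
    build_feedback,
    get_coupling,
)
from .stability import (
    check_fixed_point,
    classify_stability,
    exclusivity_check,
    jacobian_idle,
    jacobian_tripod,
)

__all__ = ["ExperimentConfig", "EXPERIMENTS", "run_experiment", "validate_params"]

log = logging.getLogger("hexacpg")


@dataclass
class ExperimentConfig:
    """Resolved configuration of one experiment run."""

    name: str
    out_dir: Path
    seed: int = 0
    reps: int = 200
    dt: float = simulate.DT_DEFAULT
    t_max: float = simulate.T_MAX_DEFAULT
    gamma: float = 1.0
    k: float = 0.0
    sigma: float = 0.01
    coupling: str = "sin"
    noise_mode: str = "white"
    connectivity: dict = field(default_factory=dict)
    feedback_weights: list | None = None
    extra: dict = field(default_factory=dict)

    def model_params(self) -> ModelParams:
        conn = ConnectivityParams(**self.connectivity)
        return ModelParams(
            gamma=self.gamma,
            k=self.k,
            sigma=self.sigma,
            A=build_connectivity(conn),
            C=build_feedback(self.feedback_weights, self.k),
            coupling=get_coupling(self.coupling),
            noise_mode=self.noise_mode,
        )

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d


def validate_params(cfg: ExperimentConfig) -> dict:
    """Check a configuration against the model's constraints.

    Reports, by name: the coupling-sign condition Gamma*H'(0) > 0, the
    connectivity sign constraints (metathoracic anti-phase, rostral
    in-phase), row normalization, and — numerically — non-positivity of the
    idle spectrum.
    """
    problems = []
    fn = get_coupling(cfg.coupling)
    if not cfg.gamma * fn.dh0 > 0:
        problems.append("coupling-sign condition Gamma*H'(0) > 0 violated")
    conn = ConnectivityParams(**cfg.connectivity)
    problems += conn.validate()
    if not problems:
        mp = cfg.model_params().with_(k=0.0)
        w = np.linalg.eigvals(jacobian_idle(mp))
        if w.real.max() > 1e-9 * max(np.linalg.norm(jacobian_idle(mp)), 1.0):
            problems.append("idle spectrum has a positive eigenvalue (synchronous state unstable)")
    return {"valid": not problems, "problems": problems}


# ---------------------------------------------------------------------------
# Experiment implementations
# ---------------------------------------------------------------------------

def _exp_fixedpoints(cfg: ExperimentConfig, out: Path) -> None:
    mp = cfg.model_params()
    res = {
        "idle_residual": check_fixed_point(IDLE, mp),
        "tripod_residual": check_fixed_point(TRIPOD, mp),
    }
    (out / "fixedpoints.json").write_text(json.dumps(res, indent=2))


def _exp_spectra(cfg: ExperimentConfig, out: Path) -> None:
    mp = cfg.model_params()
    idle = classify_stability(jacobian_idle(mp))
    tripod = classify_stability(jacobian_tripod(mp))
    payload = {
        "idle": json.loads(idle.to_json()),
        "tripod": json.loads(tripod.to_json()),
    }
    if cfg.k == 0:
        rep = exclusivity_check(
            ConnectivityParams(**cfg.connectivity), cfg.gamma, cfg.coupling
        )
        payload["exclusivity"] = {
            "ratio": rep["ratio"],
            "proportional": rep["proportional"],
            "sign_flip_equivalence": rep["sign_flip_equivalence"],
            "pairs": [[[a.real, a.imag], [b.real, b.imag]] for a, b in rep["pairs"]],
        }
    (out / "spectra.json").write_text(json.dumps(payload, indent=2))


def _exp_bouts(cfg: ExperimentConfig, out: Path) -> None:
    """A handful of example bout trajectories plus the ensemble labels."""
    mp = cfg.model_params()
    n_traces = int(cfg.extra.get("n_traces", 5))
    for i in range(n_traces):
        rec = simulate.run_bout(mp, dt=cfg.dt, t_max=cfg.t_max, seed=cfg.seed + i)
        rec.trajectory.to_frame().to_csv(out / f"bout_{i}.csv", index=False)
    records = simulate.run_bouts(mp, cfg.reps, dt=cfg.dt, t_max=cfg.t_max, seed=cfg.seed)
    df = pd.DataFrame(
        {
            "duration_last015": [r.duration_last015 for r in records],
            "duration_halflife": [r.duration_halflife for r in records],
            "drop_interval": [r.drop_interval for r in records],
            "label": [r.label for r in records],
        }
    )
    df.to_csv(out / "bout_records.csv", index=False)


def _exp_sweep_k(cfg: ExperimentConfig, out: Path) -> None:
    grid = cfg.extra.get("k_grid", [0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0])
    res = simulate.sweep_rho(
        grid, cfg.model_params(), n=cfg.reps, dt=cfg.dt, t_max=cfg.t_max, seed=cfg.seed
    )
    res.table.to_csv(out / "rho_vs_k.csv", index=False)


def _exp_distribution(cfg: ExperimentConfig, out: Path) -> None:
    mp = cfg.model_params()
    records = simulate.run_bouts(mp, cfg.reps, dt=cfg.dt, t_max=cfg.t_max, seed=cfg.seed)
    dist = simulate.duration_distribution(records)
    if "fit_declined" in dist:
        payload = {"fit_declined": dist["fit_declined"]}
    else:
        payload = {
            "mode": dist["mode"],
            "tail_rate": dist["tail_rate"],
            "tail_n": dist["tail_n"],
            "semilog_r2": dist["semilog_r2"],
        }
        pd.DataFrame(
            {"bin_left": dist["edges"][:-1], "bin_right": dist["edges"][1:], "density": dist["density"]}
        ).to_csv(out / "duration_density.csv", index=False)
    (out / "duration_fit.json").write_text(json.dumps(payload, indent=2))


def _exp_tau_gamma(cfg: ExperimentConfig, out: Path) -> None:
    grid = cfg.extra.get("gamma_grid", [0.5, 1.0, 2.0, 4.0])
    mp = cfg.model_params().with_(k=cfg.extra.get("k_fixed", 1.0))
    res = simulate.sweep_tau(
        "gamma", grid, mp, n=max(30, cfg.reps // 4), dt=cfg.dt, t_max=cfg.t_max, seed=cfg.seed
    )
    res.table["tau_pred"] = [theory.predict_tau(g, cfg.sigma, cfg.coupling) for g in res.table["gamma"]]
    res.table.to_csv(out / "tau_vs_gamma.csv", index=False)
    (out / "tau_gamma_fit.json").write_text(json.dumps(res.fit, indent=2))


def _exp_tau_sigma(cfg: ExperimentConfig, out: Path) -> None:
    grid = cfg.extra.get("sigma_grid", [1e-3, 1e-2, 1e-1])
    mp = cfg.model_params().with_(k=cfg.extra.get("k_fixed", 1.0))
    res = simulate.sweep_tau(
        "sigma", grid, mp, n=max(30, cfg.reps // 4), dt=cfg.dt, t_max=cfg.t_max, seed=cfg.seed
    )
    res.table["tau_pred"] = [theory.predict_tau(cfg.gamma, s, cfg.coupling) for s in res.table["sigma"]]
    res.table.to_csv(out / "tau_vs_sigma.csv", index=False)
    (out / "tau_sigma_fit.json").write_text(json.dumps(res.fit, indent=2))


def _exp_synth_empirical(cfg: ExperimentConfig, out: Path) -> None:
    ens = boutstats.generate_synthetic_bouts(n=cfg.extra.get("n_bouts", 43), seed=cfg.seed)
    boutstats.average_bouts(ens).to_csv(out / "mean_bout.csv", index=False)
    durations = [tr.drop_center for tr in ens.traces]
    if len(durations) >= 30:
        fit = boutstats.fit_exponential(durations, shift="auto")
        (out / "duration_fit.json").write_text(json.dumps(fit, indent=2))


EXPERIMENTS = {
    "fixedpoints": _exp_fixedpoints,
    "spectra": _exp_spectra,
    "fig3_bouts": _exp_bouts,
    "fig4_sweep_k": _exp_sweep_k,
    "fig4_distribution": _exp_distribution,
    "fig5_tau_gamma": _exp_tau_gamma,
    "fig5_tau_sigma": _exp_tau_sigma,
    "synth_empirical": _exp_synth_empirical,
}


def run_experiment(cfg: ExperimentConfig) -> Path:
    """Run a named experiment, writing results, manifest and log to disk."""
    if cfg.name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {cfg.name!r}; known: {sorted(EXPERIMENTS)}")
    report = validate_params(cfg)
    if not report["valid"]:
        raise ValueError("invalid configuration: " + "; ".join(report["problems"]))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    EXPERIMENTS[cfg.name](cfg, out)
    elapsed = time.perf_counter() - t0
    manifest = cfg.manifest()
    manifest["elapsed_seconds"] = round(elapsed, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("experiment %s finished in %.2fs -> %s", cfg.name, elapsed, out)
    return out
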