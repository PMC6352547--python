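"""Closed-form perturbation theory of the metastable double-tripod bout.

Linearizing the dynamics around the double-tripod gait, a small perturbation
dphi(0) evolves as

    dphi(t) = sum_i B_i v_i exp(lam_i^Tri t),

where v_i are the eigenvectors of the tripod Jacobian and the coefficients
B_i are obtained by biorthogonal projection (A is non-normal, so left
eigenvectors are required).  Noise of scale sigma sets the coefficient
magnitudes: E[sum_i B_i^2] = 6 sigma^2, i.e. B_i ~ sigma.  The uniform mode
(a global phase shift, zero eigenvalue) carries no gait information, so B_5
is zeroed by convention.

With feedback k >~ Gamma the four generic modes decay on the fast timescale
tau0 ~ 1/k, leaving the single unstable alternating mode, which grows on the
slow timescale tau6 = -1/(2 Gamma H'(pi)).  To first order the order
parameters then follow

    xi_Tri(t) ~= 1,        xi_Idl(t) ~= (sigma / sqrt(6)) exp(t / tau6),

valid while sigma * exp(t / tau6) << 1, and the bout lifetime is

    tau = -tau6 * ln(sigma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import CouplingFunction, get_coupling
from .stability import SpectralReport, classify_stability

__all__ = [
    "PerturbationDecomposition",
    "decompose_perturbation",
    "propagate_linear",
    "predict_order_params",
    "predict_tau",
    "tau6_timescale",
]

#: conditioning bound above which the eigenbasis is flagged as near-degenerate
CONDITION_WARN = 1e8

#: sigma * exp(t / tau6) above this is outside the linearized regime
VALIDITY_LEVEL = 0.5


def tau6_timescale(gamma: float, fn: CouplingFunction | str = "sin") -> float:
    """Slow divergence timescale tau6 = -1/(2 Gamma H'(pi))."""
    if isinstance(fn, str):
        fn = get_coupling(fn)
    if gamma * fn.dhpi >= 0:
        raise ValueError("tau6 requires Gamma * H'(pi) < 0")
    return -1.0 / (2.0 * gamma * fn.dhpi)


@dataclass
class PerturbationDecomposition:
    """A perturbation expressed in the eigenbasis of the tripod Jacobian."""

    dphi0: np.ndarray             # the raw initial perturbation
    report: SpectralReport        # spectrum and (bi)eigenvectors of J^Tri
    coefficients: np.ndarray      # B_i, with the uniform mode already zeroed
    raw_coefficients: np.ndarray  # B_i before zeroing B_5
    mode_amplitudes: np.ndarray   # b_i = v_i^H dphi0 against unit-norm eigenvectors
    uniform_index: int
    reconstruction_residual: float
    condition_warning: bool
    tau0: float                   # fast decay timescale (from the decaying modes)
    tau6: float                   # slow divergence timescale (alternating mode)


def decompose_perturbation(dphi0: np.ndarray, J: np.ndarray) -> PerturbationDecomposition:
    """Project a perturbation onto the eigenmodes of a tripod Jacobian.

    Coefficients are computed via the left eigenvectors (biorthogonal
    projection); the component along the uniform zero mode is then dropped,
    since a global phase shift has no effect on the gait.  The reconstruction
    residual ``||sum_i B_i v_i - dphi0||`` is reported *before* zeroing and
    should be at machine precision for a diagonalizable Jacobian.

    Because the Jacobian is non-normal, its eigenbasis is oblique, and two
    per-mode quantities differ: the expansion coefficients B_i (exact
    propagation) and the ``mode_amplitudes`` b_i = v_i^H dphi0 against the
    unit-norm right eigenvectors.  It is the latter that obey the noise
    scaling E[sum_i b_i^2] = 6 sigma^2 for i.i.d. N(0, sigma^2) components,
    irrespective of the basis angles.
    """
    dphi0 = np.asarray(dphi0, dtype=float)
    rep = classify_stability(np.asarray(J, dtype=float))
    cond = float(np.linalg.cond(rep.right))
    # biorthogonal projection: B = L^H dphi0 with L^H R = I
    B = rep.left.conj().T @ dphi0
    resid = float(np.linalg.norm(rep.right @ B - dphi0))
    vhat = rep.right / np.linalg.norm(rep.right, axis=0)
    amplitudes = vhat.conj().T @ dphi0
    ui = rep.uniform_index
    B_kept = B.copy()
    B_kept[ui] = 0.0
    # fast timescale from the most slowly decaying of the strictly stable modes
    neg = rep.eigenvalues.real[rep.eigenvalues.real < -rep.zero_tol * max(np.linalg.norm(J), 1.0)]
    tau0 = float(-1.0 / neg.max()) if neg.size else math.inf
    lam6 = rep.alternating_eigenvalue.real
    tau6 = 1.0 / lam6 if lam6 > 0 else math.inf
    return PerturbationDecomposition(
        dphi0=dphi0,
        report=rep,
        coefficients=B_kept,
        raw_coefficients=B,
        mode_amplitudes=amplitudes,
        uniform_index=ui,
        reconstruction_residual=resid,
        condition_warning=cond > CONDITION_WARN,
        tau0=tau0,
        tau6=tau6,
    )


def propagate_linear(decomp: PerturbationDecomposition, t) -> np.ndarray:
    """Evolve the decomposed perturbation: sum_i B_i v_i exp(lam_i t).

    ``t`` may be a scalar or a grid; returns shape (6,) or (len(t), 6).  The
    result is real up to round-off (complex modes come in conjugate pairs) and
    is returned as its real part.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    w = decomp.report.eigenvalues
    modes = decomp.report.right * decomp.coefficients  # columns B_i v_i
    out = np.real(np.exp(np.outer(t_arr, w)) @ modes.T)
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out


def predict_order_params(sigma: float, tau6: float, t) -> dict:
    """First-order analytic bout profile on the double-tripod plateau.

    Returns xi_Tri (identically 1 to first order), xi_Idl =
    (sigma/sqrt(6)) * exp(t/tau6), and a per-point validity mask for the
    linearized regime sigma * exp(t/tau6) << 1.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t = np.asarray(t, dtype=float)
    growth = np.exp(t / tau6)
    xi_idl = sigma / math.sqrt(6.0) * growth
    xi_tri = np.ones_like(xi_idl)
    valid = sigma * growth < VALIDITY_LEVEL
    return {"xi_tri": xi_tri, "xi_idl": xi_idl, "valid": valid}


def predict_tau(gamma: float, sigma: float, fn: CouplingFunction | str = "sin") -> float:
    """Predicted bout lifetime tau = -tau6 * ln(sigma).

    The plateau ends when the exponentially growing perturbation
    sigma * exp(t/tau6) reaches order one.  Requires 0 < sigma < 1 and
    Gamma * H'(pi) < 0.
    """
    if not 0.0 < sigma < 1.0:
        raise ValueError("prediction requires 0 < sigma < 1")
    return -tau6_timescale(gamma, fn) * math.log(sigma)
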