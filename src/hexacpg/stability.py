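"""Linear stability of the hexapod gaits: Jacobians, spectra, exclusivity.

Around a fixed point phi* the linearized dynamics are d(dphi)/dt = J dphi with

    J_nm = Gamma * (A_nm H'(phi_m - phi_n) - delta_nm sum_j A_nj H'(phi_j - phi_n))
           + k * H'(f_n(phi) - phi_n) * (C_nm - delta_nm).

At the idling gait all phase differences vanish, giving the closed form
J^Idl = Gamma H'(0) [A - diag(rowsum A)] + k H'(0) (C - I); at the
double-tripod gait every endogenous link spans the two trios, so the
differences are +-pi and J^Tri = Gamma H'(pi) [A - diag(rowsum A)]
+ k H'(0) (C - I).  With k = 0 the two Jacobians are exact negatives of one
another (for H = sin), which makes the stability of idling and of the
double-tripod mutually exclusive: Re(lam_i^Idl) <= 0  <=>  Re(lam_i^Tri) >= 0.

Two structural modes recur throughout: the uniform vector (a global phase
shift, always a zero mode) and the alternating vector (1,-1,...)/sqrt(6),
which measures tripod-splitting and carries the eigenvalues -2*Gamma*H'(0)
(idling) and -2*Gamma*H'(pi) (double-tripod, any k).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .network import (
    ALTERNATING,
    N_LEGS,
    UNIFORM,
    ConnectivityParams,
    CouplingFunction,
    ModelParams,
    build_connectivity,
    drift,
    feedback_field,
    get_coupling,
)

__all__ = [
    "SpectralReport",
    "jacobian_general",
    "jacobian_idle",
    "jacobian_tripod",
    "check_fixed_point",
    "classify_stability",
    "exclusivity_check",
    "alternating_eigenvalue",
]

#: eigenvalues with |Re| below ZERO_TOL * ||J|| are treated as structural zeros
ZERO_TOL = 1e-9


def jacobian_general(phi: np.ndarray, mp: ModelParams) -> np.ndarray:
    """Jacobian of the deterministic drift at an arbitrary state."""
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (N_LEGS,):
        raise ValueError("state must be a 6-vector")
    H = mp.coupling
    diff = phi[None, :] - phi[:, None]  # diff[n, m] = phi_m - phi_n
    AH = mp.A * H.prime(diff)
    J = mp.gamma * (AH - np.diag(AH.sum(axis=1)))
    # d f_n / d phi_m = C_nm for the linear feedback
    fb_slope = H.prime(feedback_field(phi, mp) - phi)
    J += mp.k * fb_slope[:, None] * (mp.C - np.eye(N_LEGS))
    return J


def jacobian_idle(mp: ModelParams) -> np.ndarray:
    """Closed-form Jacobian at the idling (synchronous) gait."""
    dh0 = mp.coupling.dh0
    lap = mp.A - np.diag(mp.A.sum(axis=1))
    return mp.gamma * dh0 * lap + mp.k * dh0 * (mp.C - np.eye(N_LEGS))


def jacobian_tripod(mp: ModelParams) -> np.ndarray:
    """Closed-form Jacobian at the double-tripod gait.

    The endogenous part picks up H'(pi) (every link spans the trios), the
    feedback part H'(0) (each trio is internally in phase, so f_n - phi_n = 0).
    """
    dh0, dhpi = mp.coupling.dh0, mp.coupling.dhpi
    lap = mp.A - np.diag(mp.A.sum(axis=1))
    return mp.gamma * dhpi * lap + mp.k * dh0 * (mp.C - np.eye(N_LEGS))


def check_fixed_point(phi: np.ndarray, mp: ModelParams) -> float:
    """Max-norm residual of the fixed-point condition (0 at a true gait)."""
    return float(np.max(np.abs(drift(phi, mp))))


@dataclass
class SpectralReport:
    """Eigendecomposition of a gait Jacobian with a stability verdict.

    Eigenvalues are sorted by descending real part.  ``right`` and ``left``
    hold the corresponding eigenvectors as columns, biorthonormalized so that
    left^H @ right = I (needed for non-normal A).  ``classification`` is
    "stable" if all eigenvalues off the structural zero mode(s) have strictly
    negative real part, "unstable" if any is positive beyond the zero
    tolerance, "marginal" otherwise.  ``uniform_index``/``alternating_index``
    locate the modes with maximal overlap with the uniform and alternating
    vectors.
    """

    jacobian: np.ndarray
    eigenvalues: np.ndarray
    right: np.ndarray
    left: np.ndarray
    classification: str
    uniform_index: int
    alternating_index: int
    zero_tol: float = ZERO_TOL
    mode_overlaps: dict = field(default_factory=dict)

    @property
    def uniform_eigenvalue(self) -> complex:
        return complex(self.eigenvalues[self.uniform_index])

    @property
    def alternating_eigenvalue(self) -> complex:
        return complex(self.eigenvalues[self.alternating_index])

    def to_json(self, path=None) -> str:
        payload = {
            "eigenvalues": [[z.real, z.imag] for z in self.eigenvalues],
            "classification": self.classification,
            "uniform_index": self.uniform_index,
            "alternating_index": self.alternating_index,
            "uniform_overlap": self.mode_overlaps.get("uniform"),
            "alternating_overlap": self.mode_overlaps.get("alternating"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _biorthonormalize(w, vr, vl):
    """Scale left eigenvectors so that vl^H vr = I (generic, diagonalizable case)."""
    scale = np.einsum("ij,ij->j", vl.conj(), vr)
    bad = np.abs(scale) < 1e-12
    if np.any(bad):
        # near-degenerate pair: fall back to pseudo-inverse left vectors
        vl = np.linalg.pinv(vr).conj().T
        scale = np.einsum("ij,ij->j", vl.conj(), vr)
    return vl / scale.conj()


def classify_stability(J: np.ndarray, *, zero_tol: float = ZERO_TOL) -> SpectralReport:
    """Full spectral analysis and stability classification of a Jacobian."""
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError("J must be square")
    try:
        w, vl, vr = scipy.linalg.eig(J, left=True, right=True)
    except Exception as exc:  # pragma: no cover - LAPACK failure is exotic
        raise RuntimeError(f"eigendecomposition failed: {exc}") from exc
    order = np.argsort(-w.real, kind="stable")
    w, vr, vl = w[order], vr[:, order], vl[:, order]
    vl = _biorthonormalize(w, vr, vl)

    scale = max(np.linalg.norm(J), 1.0)
    tol = zero_tol * scale
    is_zero = np.abs(w.real) < tol

    u_overlap = np.abs(UNIFORM @ vr) / np.linalg.norm(vr, axis=0)
    a_overlap = np.abs(ALTERNATING @ vr) / np.linalg.norm(vr, axis=0)
    ui = int(np.argmax(u_overlap))
    ai = int(np.argmax(a_overlap))

    rest = w.real[~is_zero]
    if rest.size and rest.max() > tol:
        classification = "unstable"
    elif rest.size == 0 or rest.max() < -tol:
        # require the structural zero to be simple for a "stable" verdict
        classification = "stable" if is_zero.sum() <= 1 else "marginal"
    else:
        classification = "marginal"

    return SpectralReport(
        jacobian=J,
        eigenvalues=w,
        right=vr,
        left=vl,
        classification=classification,
        uniform_index=ui,
        alternating_index=ai,
        zero_tol=zero_tol,
        mode_overlaps={"uniform": float(u_overlap[ui]), "alternating": float(a_overlap[ai])},
    )


def alternating_eigenvalue(J: np.ndarray) -> complex:
    """Eigenvalue of the mode with maximal overlap with (1,-1,1,-1,1,-1)."""
    return classify_stability(J).alternating_eigenvalue


def exclusivity_check(
    params: ConnectivityParams | np.ndarray = None,
    gamma: float = 1.0,
    coupling: CouplingFunction | str = "sin",
) -> dict:
    """Verify the idle/double-tripod mutual-exclusivity theorem at k = 0.

    Without feedback the two gait Jacobians are exactly proportional,
    J^Tri = [H'(pi)/H'(0)] J^Idl with a negative ratio, so each eigenvalue
    pair satisfies lam^Tri = ratio * lam^Idl and the stability of one gait
    forces the instability of the other.  Returns the matched pairs, the
    ratio, and booleans for the proportionality and the sign-flip
    equivalence.
    """
    if isinstance(coupling, str):
        coupling = get_coupling(coupling)
    if params is None:
        A = build_connectivity()
    elif isinstance(params, ConnectivityParams):
        A = build_connectivity(params)
    else:
        A = np.asarray(params, dtype=float)
    mp = ModelParams(gamma=gamma, k=0.0, sigma=0.0, A=A, coupling=coupling)
    J_idl = jacobian_idle(mp)
    J_tri = jacobian_tripod(mp)
    ratio = coupling.dhpi / coupling.dh0
    w_idl = np.sort_complex(np.linalg.eigvals(J_idl))
    w_tri_pred = np.sort_complex(ratio * w_idl)
    w_tri = np.sort_complex(np.linalg.eigvals(J_tri))
    scale = max(np.max(np.abs(w_idl)), 1.0)
    proportional = bool(np.allclose(w_tri, w_tri_pred, atol=1e-9 * scale))
    tol = 1e-9 * scale
    sign_flip = all(
        (li.real <= tol) == (lt.real >= -tol)
        for li, lt in zip(w_idl, ratio * w_idl)
    )
    return {
        "ratio": ratio,
        "idle_eigenvalues": w_idl,
        "tripod_eigenvalues": w_tri,
        "pairs": list(zip(w_idl, ratio * w_idl)),
        "proportional": proportional,
        "sign_flip_equivalence": sign_flip,
    }
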