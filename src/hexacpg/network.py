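"""Hexapod CPG network: leg indexing, connectivity, feedback, and phase dynamics.

Each of the six legs carries one central pattern generator, reduced to a single
phase oscillator phi_n(t).  The deterministic drift of the network is

    dphi_n/dt = Gamma * sum_m A_nm H(phi_m - phi_n) + k * H(f_n(phi) - phi_n)

where ``A`` is the endogenous (in vitro) wiring diagram, ``H`` a 2*pi-periodic
coupling function with H(0) = H(pi) = 0 and H'(pi) < 0 < H'(0), and
``f_n(phi) = sum_m C_nm phi_m`` a tripod-reinforcing sensory feedback of
strength ``k``.  Additive white noise of scale sigma completes the stochastic
model (see :mod:`hexacpg.simulate`).

Leg/node numbering (0-based internally, legs labelled 1..6 in I/O):

    1 = right pro,  2 = left pro,
    3 = left meso,  4 = right meso,
    5 = right meta, 6 = left meta.

With this labelling the two tripod trios are the odd legs {1,3,5} and the even
legs {2,4,6}; the double-tripod gait is phi = (0, pi, 0, pi, 0, pi) and the
mirror permutation M swaps legs within each segment: 1<->2, 3<->4, 5<->6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "N_LEGS",
    "IDLE",
    "TRIPOD",
    "MIRROR_PERM",
    "MIRROR",
    "TRIO_ODD",
    "TRIO_EVEN",
    "ALTERNATING",
    "UNIFORM",
    "LEG_LABELS",
    "CouplingFunction",
    "register_coupling",
    "get_coupling",
    "ConnectivityParams",
    "build_connectivity",
    "validate_connectivity",
    "build_feedback",
    "ModelParams",
    "drift",
    "feedback_field",
    "connectivity_to_csv",
    "connectivity_from_csv",
    "load_config",
]

# ---------------------------------------------------------------------------
# Leg indexing
# ---------------------------------------------------------------------------

N_LEGS = 6

#: idling (all-in-phase) gait
IDLE = np.zeros(N_LEGS)

#: double-tripod gait: the two trios locked in anti-phase
TRIPOD = np.array([0.0, np.pi, 0.0, np.pi, 0.0, np.pi])

#: left-right mirror permutation (0-based): swaps the two legs of each segment
MIRROR_PERM = np.array([1, 0, 3, 2, 5, 4])

#: permutation matrix of the mirror, M @ phi == phi[MIRROR_PERM]
MIRROR = np.eye(N_LEGS)[MIRROR_PERM]

TRIO_ODD = np.array([0, 2, 4])   # legs 1, 3, 5
TRIO_EVEN = np.array([1, 3, 5])  # legs 2, 4, 6

#: normalized alternating mode (1,-1,1,-1,1,-1)/sqrt(6)
ALTERNATING = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0]) / np.sqrt(6)

#: normalized uniform mode (1,...,1)/sqrt(6)
UNIFORM = np.ones(N_LEGS) / np.sqrt(6)

LEG_LABELS = (
    "R-pro", "L-pro", "L-meso", "R-meso", "R-meta", "L-meta",
)


# ---------------------------------------------------------------------------
# Coupling function H
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingFunction:
    """A 2*pi-periodic coupling function with an evaluable derivative.

    Constraints: H(0) = H(pi) = 0 and H'(pi) < 0 < H'(0).  Inputs are reduced
    modulo 2*pi before evaluation so the periodic extension is exact even for
    user-supplied functions defined only on [0, 2*pi).
    """

    name: str
    h: Callable[[np.ndarray], np.ndarray]
    dh: Callable[[np.ndarray], np.ndarray]

    def __call__(self, x):
        return self.h(np.mod(x, 2.0 * np.pi))

    def prime(self, x):
        return self.dh(np.mod(x, 2.0 * np.pi))

    @property
    def dh0(self) -> float:
        """H'(0) — slope at the in-phase lock."""
        return float(self.dh(np.asarray(0.0)))

    @property
    def dhpi(self) -> float:
        """H'(pi) — slope at the anti-phase lock."""
        return float(self.dh(np.asarray(np.pi)))


_COUPLING_REGISTRY: dict[str, CouplingFunction] = {}


def register_coupling(name: str, h, dh, *, n_check: int = 64) -> CouplingFunction:
    """Validate and register a coupling function preset.

    Raises ``ValueError`` if H(0) or H(pi) is nonzero, if the derivative sign
    conditions H'(pi) < 0 < H'(0) fail, or if ``h`` is visibly non-periodic on
    a sample grid.
    """
    fn = CouplingFunction(name, h, dh)
    if abs(fn(0.0)) > 1e-12 or abs(fn(np.pi)) > 1e-12:
        raise ValueError(f"coupling {name!r}: H(0) and H(pi) must both vanish")
    if not (fn.dh0 > 0.0):
        raise ValueError(f"coupling {name!r}: H'(0) must be positive")
    if not (fn.dhpi < 0.0):
        raise ValueError(f"coupling {name!r}: H'(pi) must be negative")
    x = np.linspace(0.0, 2.0 * np.pi, n_check, endpoint=False)
    if not np.allclose(fn(x), fn(x + 2.0 * np.pi), atol=1e-10):
        raise ValueError(f"coupling {name!r}: H must be 2*pi-periodic")
    _COUPLING_REGISTRY[name] = fn
    return fn


def get_coupling(name: str) -> CouplingFunction:
    try:
        return _COUPLING_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown coupling {name!r}; registered: {sorted(_COUPLING_REGISTRY)}"
        ) from None


register_coupling("sin", np.sin, np.cos)


# ---------------------------------------------------------------------------
# Endogenous connectivity A
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConnectivityParams:
    """The seven independent weights of the 14-link wiring diagram.

    ``l1, l2, l3`` are the contralateral couplings within the pro-, meso- and
    metathoracic segments (both directions each); ``b1, b2`` the descending
    ipsilateral links pro->meso and meso->meta; ``f1, f2`` the ascending links
    meso->pro and meta->meso (each on both sides).  Sign convention: positive
    weights favour in-phase locking, negative anti-phase.  The metathoracic
    contralateral weight is negative (l3 < 0), reflecting the anti-phase
    bilateral preference of the metathoracic ganglion, while the rostral
    segments prefer in-phase (l1, l2 > 0).

    The defaults are row-normalized surrogates (each row of A sums to 1):
    l1 + f1 = 1, b1 + l2 + f2 = 1, b2 + l3 = 1.
    """

    l1: float = 0.5
    l2: float = 0.4
    l3: float = -0.5
    b1: float = 0.3
    b2: float = 1.5
    f1: float = 0.5
    f2: float = 0.3

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("l1", "l2", "l3", "b1", "b2", "f1", "f2")}

    def validate(self) -> list[str]:
        """Return a list of violated constraints (empty if valid)."""
        problems = []
        vals = self.as_dict()
        if not all(math.isfinite(v) for v in vals.values()):
            problems.append("non-finite connectivity weight")
        if not self.l3 < 0:
            problems.append("metathoracic anti-phase preference requires l3 < 0")
        if not (self.l1 > 0 and self.l2 > 0):
            problems.append("rostral in-phase preference requires l1, l2 > 0")
        for name, s in self.row_sums().items():
            if not math.isclose(s, 1.0, abs_tol=1e-9):
                problems.append(f"{name} row sum {s:.6g} != 1 (row normalization)")
        return problems

    def row_sums(self) -> dict[str, float]:
        return {
            "pro": self.l1 + self.f1,
            "meso": self.b1 + self.l2 + self.f2,
            "meta": self.b2 + self.l3,
        }


def build_connectivity(
    params: ConnectivityParams = ConnectivityParams(), *, force: bool = False
) -> np.ndarray:
    """Place the 14 directed links into the 6x6 coupling matrix A.

    ``A[n, m]`` weights the influence of leg m on leg n.  The left-right
    symmetry A = M A M holds by construction; every link joins opposite trios,
    so the alternating vector is an exact eigenvector: A v6 = -v6 whenever the
    rows sum to 1.

    Parameters violating the sign constraints are rejected unless
    ``force=True`` (row-normalization violations are reported by
    ``params.validate()`` but only warned about here, since A itself is
    validated separately).
    """
    vals = params.as_dict()
    if not all(math.isfinite(v) for v in vals.values()):
        raise ValueError("connectivity weights must be finite")
    if not force:
        sign_problems = [
            p for p in params.validate() if "row sum" not in p and "finite" not in p
        ]
        if sign_problems:
            raise ValueError("; ".join(sign_problems) + " (pass force=True to override)")

    A = np.zeros((N_LEGS, N_LEGS))
    l1, l2, l3 = params.l1, params.l2, params.l3
    b1, b2 = params.b1, params.b2
    f1, f2 = params.f1, params.f2
    # contralateral, both directions within each segment
    A[0, 1] = A[1, 0] = l1   # pro:  R1 <-> L2
    A[2, 3] = A[3, 2] = l2   # meso: L3 <-> R4
    A[4, 5] = A[5, 4] = l3   # meta: R5 <-> L6
    # descending ipsilateral pro->meso and meso->meta, both sides
    A[3, 0] = A[2, 1] = b1   # R1 -> R4, L2 -> L3
    A[4, 3] = A[5, 2] = b2   # R4 -> R5, L3 -> L6
    # ascending ipsilateral meso->pro and meta->meso, both sides
    A[0, 3] = A[1, 2] = f1   # R4 -> R1, L3 -> L2
    A[3, 4] = A[2, 5] = f2   # R5 -> R4, L6 -> L3
    return A


def validate_connectivity(A: np.ndarray, *, atol: float = 1e-9) -> list[str]:
    """Check the structural invariants of a coupling matrix.

    Returns the list of violations (empty if A is a valid wiring diagram):
    zero diagonal, at most 14 directed links, left-right mirror symmetry,
    bipartiteness with respect to the trio partition, and unit row sums.
    """
    A = np.asarray(A, dtype=float)
    problems = []
    if A.shape != (N_LEGS, N_LEGS):
        return [f"shape {A.shape} != (6, 6)"]
    if np.any(np.abs(np.diag(A)) > atol):
        problems.append("nonzero diagonal")
    if np.count_nonzero(A) > 14:
        problems.append(f"{np.count_nonzero(A)} links > 14")
    if not np.allclose(A, MIRROR @ A @ MIRROR, atol=atol):
        problems.append("left-right mirror symmetry A = M A M violated")
    same_trio = (np.add.outer(np.arange(6), np.arange(6)) % 2) == 0
    if np.any(np.abs(A[same_trio & ~np.eye(6, dtype=bool)]) > atol):
        problems.append("within-trio link present (A must be trio-bipartite)")
    if not np.allclose(A.sum(axis=1), 1.0, atol=atol):
        problems.append(f"row sums {A.sum(axis=1)} != 1")
    return problems


# ---------------------------------------------------------------------------
# Sensory feedback C
# ---------------------------------------------------------------------------

def build_feedback(
    trio_weights: Sequence[float] | None = None, k: float = 0.0
) -> np.ndarray:
    """Build the feedback matrix C from per-trio mixing weights.

    ``f_n(phi) = sum_m C_nm phi_m`` averages each leg's phase with its own
    trio; C_nm = 0 across trios and every row sums to 1.  ``trio_weights``
    gives the three nonnegative weights applied within a trio in leg order
    (self-position determined by n); ``None`` means the uniform average
    (1/3, 1/3, 1/3), which makes C an exact projector (C @ C == C).

    The feedback strength ``k`` is validated here but stored on
    :class:`ModelParams`.
    """
    if k < 0:
        raise ValueError("feedback strength k must be nonnegative")
    if trio_weights is None:
        w = np.full(3, 1.0 / 3.0)
    else:
        w = np.asarray(trio_weights, dtype=float)
        if w.shape != (3,):
            raise ValueError("trio_weights must have length 3")
        if np.any(w < 0):
            raise ValueError("trio_weights must be nonnegative")
        if w.sum() == 0:
            raise ValueError("trio_weights must not sum to 0")
        w = w / w.sum()
    C = np.zeros((N_LEGS, N_LEGS))
    for trio in (TRIO_ODD, TRIO_EVEN):
        for pos, n in enumerate(trio):
            # roll so that index 0 of trio_weights is the self weight
            C[n, np.roll(trio, -pos)] = w
    return C


# ---------------------------------------------------------------------------
# Model parameters & drift
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of the stochastic phase model.

    Attributes
    ----------
    gamma : float
        Global endogenous coupling strength (Gamma > 0 for H'(0) > 0).
    k : float
        Sensory-feedback strength (k = 0 reproduces fictive, in vitro
        conditions; k > 0 the intact animal).
    sigma : float
        Noise scale; sigma = 0 gives deterministic dynamics.
    A, C : (6, 6) arrays
        Endogenous connectivity and feedback matrices.
    coupling : CouplingFunction
        The 2*pi-periodic H.
    noise_mode : {"white", "initial_kick"}
        "white": additive Gaussian white noise integrated with Euler-Maruyama.
        "initial_kick": a single N(0, sigma^2) perturbation of the initial
        phases, deterministic thereafter.
    """

    gamma: float = 1.0
    k: float = 0.0
    sigma: float = 0.01
    A: np.ndarray = field(default_factory=build_connectivity)
    C: np.ndarray = field(default_factory=build_feedback)
    coupling: CouplingFunction = field(default_factory=lambda: get_coupling("sin"))
    noise_mode: str = "white"

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.k < 0:
            raise ValueError("k must be nonnegative")
        if self.noise_mode not in ("white", "initial_kick"):
            raise ValueError("noise_mode must be 'white' or 'initial_kick'")
        # Gamma * H'(0) > 0 (stability of the synchronous state) is checked by
        # experiments.validate_params, not here: the drift and Jacobians are
        # well-defined for any Gamma, and degenerate values are useful limits.
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        object.__setattr__(self, "C", np.asarray(self.C, dtype=float))

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def tau6(self) -> float:
        """Slow divergence timescale of the double-tripod gait, -1/(2*Gamma*H'(pi))."""
        return -1.0 / (2.0 * self.gamma * self.coupling.dhpi)


def feedback_field(phi: np.ndarray, mp: ModelParams) -> np.ndarray:
    """The virtual-node phases f_n(phi) = sum_m C_nm phi_m.

    A linear combination of the unwrapped (real-line) phases; trajectories are
    integrated on the lift so no wrap discontinuity arises.
    """
    phi = np.asarray(phi, dtype=float)
    return phi @ mp.C.T


def drift(phi: np.ndarray, mp: ModelParams) -> np.ndarray:
    """Deterministic phase velocities for state(s) ``phi``.

    Accepts a single state of shape (6,) or a batch (..., 6); broadcasts over
    leading axes.  Depends only on phase differences, so it is exactly
    invariant under a uniform shift phi -> phi + c.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.shape[-1] != N_LEGS:
        raise ValueError("state must have 6 phases on the last axis")
    if not np.all(np.isfinite(phi)):
        raise ValueError("phases must be finite")
    H = mp.coupling
    diff = phi[..., None, :] - phi[..., :, None]  # diff[..., n, m] = phi_m - phi_n
    endo = mp.gamma * np.sum(mp.A * H(diff), axis=-1)
    fb = mp.k * H(feedback_field(phi, mp) - phi)
    return endo + fb


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def connectivity_to_csv(A: np.ndarray, path) -> None:
    """Write a 6x6 coupling matrix as CSV with leg labels as header/index."""
    import pandas as pd

    pd.DataFrame(A, index=LEG_LABELS, columns=LEG_LABELS).to_csv(path)


def connectivity_from_csv(path) -> np.ndarray:
    import pandas as pd

    A = pd.read_csv(path, index_col=0).to_numpy(dtype=float)
    if A.shape != (N_LEGS, N_LEGS):
        raise ValueError(f"expected a 6x6 matrix, got {A.shape}")
    return A


def load_config(path) -> ModelParams:
    """Build ModelParams from a TOML config file.

    Recognized sections and keys::

        [model]         gamma, k, sigma, H (coupling preset name), noise_mode
        [connectivity]  l1, l2, l3, b1, b2, f1, f2
        [feedback]      weights (length-3 list)
    """
    import tomllib

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    model = cfg.get("model", {})
    conn = cfg.get("connectivity", {})
    fb = cfg.get("feedback", {})
    params = ConnectivityParams(**conn) if conn else ConnectivityParams()
    k = float(model.get("k", 0.0))
    return ModelParams(
        gamma=float(model.get("gamma", 1.0)),
        k=k,
        sigma=float(model.get("sigma", 0.01)),
        A=build_connectivity(params),
        C=build_feedback(fb.get("weights"), k),
        coupling=get_coupling(model.get("H", "sin")),
        noise_mode=model.get("noise_mode", "white"),
    )
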