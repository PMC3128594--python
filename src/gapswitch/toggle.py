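"""Two-repressor toggle switch with variable synthesis rates.

The switch is the pair of ODEs

    dR1/dt = alpha1 * (1 - p(R2)) - beta * R1
    dR2/dt = alpha2 * (1 - p(R1)) - beta * R2

where ``p`` is the fractional occupancy of the repressor's site array.  The
synthesis rates alpha1, alpha2 stand in for positional cues: when both are
high and repression is cooperative the system is bistable (two attractors,
each with one repressor dominant); asymmetric or low rates leave a single
attractor.  Scanning (alpha1(x), alpha2(x)) along the embryo axis shows how
maternal gradients operate the switch in space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .occupancy import SiteArray, site_occupancy

__all__ = [
    "ToggleParams",
    "toggle_rhs",
    "find_attractors",
    "phase_portrait",
    "positional_attractor_scan",
]

#: default repression array: strongly cooperative, the regime of the
#: two-attractor phase portraits
DEFAULT_REPRESSION = SiteArray(K=1.0, C=5.0, N=3)


@dataclass(frozen=True)
class ToggleParams:
    """Synthesis/decay rates and the (shared) repression site array."""

    alpha1: float = 1.0
    alpha2: float = 1.0
    beta: float = 0.1
    repression: SiteArray = field(default_factory=lambda: DEFAULT_REPRESSION)

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("synthesis rates must be non-negative")

    @property
    def alpha_max(self) -> float:
        return max(self.alpha1, self.alpha2)


def toggle_rhs(state, params: ToggleParams):
    """Right-hand side (dR1/dt, dR2/dt); vectorized over trailing axes."""
    r1, r2 = np.asarray(state[0], float), np.asarray(state[1], float)
    if np.any(r1 < 0) or np.any(r2 < 0):
        raise ValueError("concentrations must be non-negative")
    d1 = params.alpha1 * (1.0 - site_occupancy(r2, params.repression)) - params.beta * r1
    d2 = params.alpha2 * (1.0 - site_occupancy(r1, params.repression)) - params.beta * r2
    return d1, d2


def _integrate_lattice(params: ToggleParams, inits: np.ndarray,
                       max_steps: int, dt: float, atol: float) -> Tuple[np.ndarray, np.ndarray]:
    """Euler-integrate a (m, 2) lattice of initial points to steady state."""
    state = inits.copy()
    converged = np.zeros(len(state), dtype=bool)
    for _ in range(max_steps):
        d1, d2 = toggle_rhs((state[:, 0], state[:, 1]), params)
        delta = np.column_stack([d1, d2]) * dt
        state = np.maximum(state + delta, 0.0)
        converged = np.max(np.abs(delta), axis=1) < atol
        if converged.all():
            break
    return state, converged


def _is_stable(point: np.ndarray, params: ToggleParams, eps: float = 1e-6) -> bool:
    """Linear stability via a finite-difference Jacobian.

    Rules out saddle points, which symmetric initial conditions can reach
    along their stable manifold.
    """
    jac = np.empty((2, 2))
    base = np.maximum(point, 0.0)
    for k in range(2):
        hi = base.copy()
        hi[k] += eps
        lo = base.copy()
        lo[k] = max(lo[k] - eps, 0.0)
        f_hi = toggle_rhs((hi[0], hi[1]), params)
        f_lo = toggle_rhs((lo[0], lo[1]), params)
        h = hi[k] - lo[k]
        jac[:, k] = [(f_hi[0] - f_lo[0]) / h, (f_hi[1] - f_lo[1]) / h]
    return bool(np.all(np.real(np.linalg.eigvals(jac)) < 0))


def find_attractors(params: ToggleParams, init_grid: int = 6,
                    tol: Optional[float] = None,
                    max_steps: int = 10_000) -> List[Tuple[float, float]]:
    """Distinct stable fixed points reached from a lattice of initial states.

    Initial conditions cover [0, alpha_max/beta]^2 on an ``init_grid`` x
    ``init_grid`` lattice; endpoints are clustered within ``tol`` (default
    1e-3 * alpha_max/beta) and each representative is verified to satisfy
    |RHS| < tol * beta.  Non-converged lattice points are excluded with a
    warning.
    """
    if init_grid < 2:
        raise ValueError("init_grid must be >= 2")
    scale = params.alpha_max / params.beta
    if tol is None:
        tol = 1e-3 * scale if scale > 0 else 1e-6
    if scale == 0:
        # no synthesis at all: the origin is the only candidate
        axis = np.array([0.0, 1.0])
    else:
        axis = np.linspace(0.0, scale, init_grid)
    inits = np.array([(a, b) for a in axis for b in axis])
    dt = 0.1 / params.beta
    endpoints, converged = _integrate_lattice(params, inits, max_steps, dt, atol=1e-9)
    if not converged.all():
        import warnings
        warnings.warn(f"{int((~converged).sum())} lattice points did not converge; excluded",
                      RuntimeWarning, stacklevel=2)
        endpoints = endpoints[converged]

    rhs_tol = max(tol * params.beta, 1e-7)
    attractors: List[np.ndarray] = []
    for point in endpoints:
        for known in attractors:
            if np.max(np.abs(point - known)) < tol:
                break
        else:
            d1, d2 = toggle_rhs((point[0], point[1]), params)
            if max(abs(float(d1)), abs(float(d2))) < rhs_tol and _is_stable(point, params):
                attractors.append(point)
    attractors.sort(key=lambda p: (round(p[0], 6), round(p[1], 6)))
    return [(float(p[0]), float(p[1])) for p in attractors]


def phase_portrait(params: ToggleParams, grid: int = 25) -> dict:
    """Sampled vector field and nullclines on [0, alpha_max/beta]^2.

    Returns a dict with the sample axes, dR1/dt and dR2/dt fields, the two
    nullclines as point arrays (located by sign change along the clamped
    axis), and the attractors.
    """
    scale = params.alpha_max / params.beta
    if scale == 0:
        scale = 1.0
    axis = np.linspace(0.0, scale, grid)
    R1, R2 = np.meshgrid(axis, axis, indexing="ij")
    d1, d2 = toggle_rhs((R1, R2), params)

    # nullcline of R1: for each R2, the R1 where dR1/dt crosses zero
    null1, null2 = [], []
    for j, r2 in enumerate(axis):
        col = d1[:, j]
        for i in range(len(axis) - 1):
            if col[i] == 0 or (col[i] > 0) != (col[i + 1] > 0):
                frac = col[i] / (col[i] - col[i + 1]) if col[i] != col[i + 1] else 0.0
                null1.append((axis[i] + frac * (axis[i + 1] - axis[i]), r2))
    for i, r1 in enumerate(axis):
        row = d2[i, :]
        for j in range(len(axis) - 1):
            if row[j] == 0 or (row[j] > 0) != (row[j + 1] > 0):
                frac = row[j] / (row[j] - row[j + 1]) if row[j] != row[j + 1] else 0.0
                null2.append((r1, axis[j] + frac * (axis[j + 1] - axis[j])))

    return {
        "axis": axis,
        "dR1": d1,
        "dR2": d2,
        "nullcline_R1": np.array(null1) if null1 else np.empty((0, 2)),
        "nullcline_R2": np.array(null2) if null2 else np.empty((0, 2)),
        "attractors": find_attractors(params),
    }


def positional_attractor_scan(alpha1_profile, alpha2_profile,
                              params: ToggleParams, init_grid: int = 5) -> dict:
    """Attractor count and winner identity for positionally varying rates.

    At every axis position x the switch is analysed with rates
    (alpha1(x), alpha2(x)); the "winner" at an attractor is the component
    with the larger concentration ("tie" within tolerance).  Returns arrays
    ``counts`` and ``winners`` (list of per-position winner labels).
    """
    a1 = np.asarray(alpha1_profile, dtype=float)
    a2 = np.asarray(alpha2_profile, dtype=float)
    if a1.shape != a2.shape:
        raise ValueError("rate profiles must share a grid")
    counts = np.zeros(a1.shape, dtype=int)
    winners: List[List[str]] = []
    for i in range(a1.size):
        local = ToggleParams(alpha1=float(a1[i]), alpha2=float(a2[i]),
                             beta=params.beta, repression=params.repression)
        att = find_attractors(local, init_grid=init_grid)
        counts[i] = len(att)
        labels = []
        for r1, r2 in att:
            span = max(r1, r2, 1e-12)
            if abs(r1 - r2) <= 1e-3 * span:
                labels.append("tie")
            else:
                labels.append("gene1" if r1 > r2 else "gene2")
        winners.append(labels)
    return {"counts": counts, "winners": winners}
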