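"""Four-gene reaction-diffusion model of the trunk gap genes.

Each gap gene A in {Hb, Kr, Kni, Gt} obeys

    dA/dt = alpha * omega_A * P_A(x, state) - beta * A  (+ diffusion)

where ``P_A`` combines the maternal positional cue of A with repression by
its toggle-switch counterpart, all expressed through fractional site
occupancies:

* Hb:  cue (Bcd AND Hb) x Kni repression;
* Kni: cue (Bcd, Hb-R repression) x Tll repression;
* Kr:  cue (dual Hb) x Gt repression;
* Gt:  cue (Bcd OR Cad, Tll repression) x Kr repression.

Synthesis potentials are normalized per gene to [0, 1] at the initial time
(maternal Hb as the Hb initial condition, other gap genes at zero) by the
multiplier ``omega_A = 1 / max_x P_A(x, 0)``, so every gene starts with the
same maximal possible synthesis rate ``alpha``.

Integration is explicit Euler (default dt = 2.2 min) on a 100-point axis
grid (dx = 5 um); diffusion is applied between Euler steps as a Gaussian
filter of standard deviation sqrt(2 D dt) with reflecting (no-flux)
boundaries.  Concentrations are clipped to [0, C_max = 50 nM].

The synthesis and decay rate constants are numerically equal when
concentrations are measured relative to C_max: the single rate parameter
``rho`` gives ``alpha = rho * C_max`` (nM/min) and ``beta = rho`` (1/min),
so an unrepressed, fully normalized gene saturates exactly at C_max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .core import C_MAX, GAP_GENES, AxisGrid, GradientSet

__all__ = [
    "ModelParams",
    "Trajectory",
    "normalizers",
    "synthesis_field",
    "euler_step",
    "diffuse",
    "run_simulation",
    "REGULATORY_LINKS",
]

#: every regulatory connection in the network ("->" activation, "-|" repression)
REGULATORY_LINKS = frozenset({
    "Bcd->Hb", "Hb->Hb", "Kni-|Hb",
    "Bcd->Kni", "Hb-|Kni", "Tll-|Kni",
    "Hb->Kr", "Hb-|Kr", "Gt-|Kr",
    "Bcd->Gt", "Cad->Gt", "Tll-|Gt", "Kr-|Gt",
    "Bcd-|Cad",
})


class ConfigError(ValueError):
    """Inconsistent model configuration (stability, unknown links, ...)."""


class DegenerateCueError(ValueError):
    """A gap gene's synthesis potential is zero everywhere at t = 0."""


@dataclass(frozen=True)
class ModelParams:
    """Global and node-specific parameters of the dynamic model.

    ``K`` is the global binding affinity shared by 12 of the 14 network
    edges; the toggle switches contribute the node-specific affinities
    ``K1`` (Hb repressing kni, the "Hb-R" array) and ``K2`` (Kr repressing
    gt).  ``C`` (cooperativity) and ``N`` (sites per array) are global, as
    are the diffusion constant ``D``, synthesis rate ``alpha`` and decay
    rate ``beta``.  ``omega`` holds the per-gene synthesis normalizers and
    is set only by :func:`normalizers`.
    """

    K: float
    K1: Optional[float] = None      # Hb -| Kni repressor affinity; None -> K
    K2: Optional[float] = None      # Kr -| Gt repressor affinity; None -> K
    C: float = 5.0
    N: int = 5
    D: float = 5.0                  # um^2 / min
    alpha: float = 5.0              # nM / min
    beta: float = 0.1               # 1 / min
    C_max: float = C_MAX
    coop: str = "chain"
    kr_rep_K: Optional[float] = None  # separate Hb-repressor affinity on Kr (off by default)
    omega: Optional[Dict[str, float]] = None
    disabled_links: FrozenSet[str] = frozenset()
    null_genes: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        for name in ("K", "C", "alpha", "beta", "C_max"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.D < 0:
            raise ConfigError("D must be non-negative")
        unknown = self.disabled_links - REGULATORY_LINKS
        if unknown:
            raise ConfigError(f"unknown regulatory link(s): {sorted(unknown)}")
        unknown_genes = set(self.null_genes) - set(GAP_GENES)
        if unknown_genes:
            raise ConfigError(f"unknown null gene(s): {sorted(unknown_genes)}")

    @classmethod
    def coupled(cls, rate: float, **kwargs) -> "ModelParams":
        """Build params with alpha = rate * C_max and beta = rate.

        This is the single-rate convention of the fitted model: synthesis
        and decay constants are numerically equal in units of C_max.
        """
        c_max = kwargs.pop("C_max", C_MAX)
        return cls(alpha=rate * c_max, beta=rate, C_max=c_max, **kwargs)

    # -- site arrays per edge --------------------------------------------
    def _array(self, K: float):
        from .occupancy import SiteArray
        return SiteArray(K=K, C=self.C, N=self.N, coop=self.coop)

    @property
    def bcd_array(self):
        """Shared array on every Bcd edge (global K)."""
        return self._array(self.K)

    @property
    def hb_array(self):
        """Hb as activator / dual regulator (global K)."""
        return self._array(self.K)

    @property
    def hb_rep_array(self):
        """Hb as dedicated repressor on kni (K1)."""
        return self._array(self.K1 if self.K1 is not None else self.K)

    @property
    def kr_rep_array(self):
        """Kr repressing gt (K2)."""
        return self._array(self.K2 if self.K2 is not None else self.K)

    @property
    def gt_rep_array(self):
        """Gt repressing Kr (global K)."""
        return self._array(self.K)

    @property
    def kni_rep_array(self):
        """Kni repressing hb (global K)."""
        return self._array(self.K)

    @property
    def cad_array(self):
        """Cad activating gt (global K)."""
        return self._array(self.K)

    @property
    def tll_array(self):
        """Tll repressing kni and gt (global K)."""
        return self._array(self.K)

    def with_omega(self, omega: Dict[str, float]) -> "ModelParams":
        return replace(self, omega=dict(omega))


@dataclass
class Trajectory:
    """Time-ordered sequence of model states."""

    times: np.ndarray
    states: List[GradientSet]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.states):
            raise ValueError("times and states length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def initial(self) -> GradientSet:
        return self.states[0]

    @property
    def final(self) -> GradientSet:
        return self.states[-1]

    def at_fraction(self, frac: float) -> GradientSet:
        """State closest to a fraction of total simulated time."""
        idx = int(round(frac * (len(self.states) - 1)))
        return self.states[idx]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (time, gene, x_percent_el, conc_nM)."""
        frames = []
        for t, state in zip(self.times, self.states):
            frame = state.to_frame()
            frame.insert(0, "time", t)
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# evaluation context: static occupancies precomputed once per run
# ---------------------------------------------------------------------------

class _Context:
    """Precomputed static occupancies and link switches for one run."""

    def __init__(self, inputs: GradientSet, params: ModelParams):
        from .occupancy import site_occupancy

        inputs.require("Bcd", "Hb_mat", "Tll")
        self.grid = inputs.grid
        self.params = params
        dis = params.disabled_links

        bcd = inputs["Bcd"]
        tll = inputs["Tll"]
        p_bcd = site_occupancy(bcd, params.bcd_array)
        p_tll = site_occupancy(tll, params.tll_array)

        # Caudal: computed from Bcd unless supplied, then a stable input
        if "Cad" in inputs:
            cad = inputs["Cad"]
        else:
            p_bcd_cad = 0.0 if "Bcd-|Cad" in dis else p_bcd
            cad = params.C_max * (1.0 - p_bcd_cad)
        self.cad = cad
        p_cad = site_occupancy(cad, params.cad_array)

        zeros = np.zeros(self.grid.n_points)
        self.pb_hb = zeros if "Bcd->Hb" in dis else p_bcd
        self.pb_kni = zeros if "Bcd->Kni" in dis else p_bcd
        self.pb_gt = zeros if "Bcd->Gt" in dis else p_bcd
        self.pc_gt = zeros if "Cad->Gt" in dis else p_cad
        self.pt_kni = zeros if "Tll-|Kni" in dis else p_tll
        self.pt_gt = zeros if "Tll-|Gt" in dis else p_tll

        self.hb_auto = "Hb->Hb" not in dis
        self.kni_on_hb = "Kni-|Hb" not in dis
        self.hbr_on_kni = "Hb-|Kni" not in dis
        self.hb_act_kr = "Hb->Kr" not in dis
        self.hb_rep_kr = "Hb-|Kr" not in dis
        self.gt_on_kr = "Gt-|Kr" not in dis
        self.kr_on_gt = "Kr-|Gt" not in dis

        self.hb_arr = params.hb_array
        self.hbr_arr = params.hb_rep_array
        self.kni_arr = params.kni_rep_array
        self.kr_arr = params.kr_rep_array
        self.gt_arr = params.gt_rep_array
        from .occupancy import SiteArray
        self.kr_hbr_arr = (
            SiteArray(params.kr_rep_K, params.C, params.N, params.coop)
            if params.kr_rep_K is not None else self.hb_arr
        )
        # stacked occupation-number polynomial coefficients for the dynamic
        # occupancies [Hb-act, Hb-rep(K1), Kni, Kr(K2), Gt, Hb-rep-on-Kr]
        # (all arrays share the global N, so one Horner pass serves them all)
        self._dyn_coeffs = np.stack([arr.weights() for arr in (
            self.hb_arr, self.hbr_arr, self.kni_arr, self.kr_arr,
            self.gt_arr, self.kr_hbr_arr)])

    def _dyn_occupancies(self, state: np.ndarray) -> np.ndarray:
        """Occupancies of the five dynamic edges (6, n), one Horner pass."""
        hb, kr, kni, gt = state
        conc = np.stack([hb, hb, kni, kr, gt, hb])
        coeffs = self._dyn_coeffs
        z = np.broadcast_to(coeffs[:, -1:], conc.shape).copy()
        for i in range(coeffs.shape[1] - 2, -1, -1):
            z *= conc
            z += coeffs[:, i:i + 1]
        return 1.0 - 1.0 / z

    def potentials(self, state: np.ndarray) -> np.ndarray:
        """Synthesis potentials P_A (4, n) for a (4, n) state [Hb,Kr,Kni,Gt]."""
        hb = state[0]
        occ = self._dyn_occupancies(state)
        p_hb, p_hbr = occ[0], occ[1]
        p_kni = occ[2] if self.kni_on_hb else 0.0
        p_kr = occ[3] if self.kr_on_gt else 0.0
        p_gt = occ[4] if self.gt_on_kr else 0.0

        P_hb = self.pb_hb * (p_hb if self.hb_auto else 0.0) * (1.0 - p_kni)
        P_kni = self.pb_kni * (1.0 - (p_hbr if self.hbr_on_kni else 0.0)) \
            * (1.0 - self.pt_kni)

        p_hb_kr_rep = occ[5]
        P_kr = (p_hb if self.hb_act_kr else 0.0) \
            * (1.0 - (p_hb_kr_rep if self.hb_rep_kr else 0.0)) \
            * (1.0 - p_gt)
        P_gt = (1.0 - (1.0 - self.pb_gt) * (1.0 - self.pc_gt)) \
            * (1.0 - self.pt_gt) * (1.0 - p_kr)

        out = np.vstack([
            np.broadcast_to(P_hb, hb.shape),
            np.broadcast_to(P_kr, hb.shape),
            np.broadcast_to(P_kni, hb.shape),
            np.broadcast_to(P_gt, hb.shape),
        ])
        for i, gene in enumerate(("Hb", "Kr", "Kni", "Gt")):
            if gene in self.params.null_genes:
                out[i] = 0.0
        return out


_STATE_ORDER = ("Hb", "Kr", "Kni", "Gt")


def _initial_state(inputs: GradientSet) -> np.ndarray:
    n = inputs.grid.n_points
    state = np.zeros((4, n))
    state[0] = inputs["Hb_mat"]
    return state


def _state_to_set(state: np.ndarray, grid: AxisGrid) -> GradientSet:
    return GradientSet({g: state[i].copy() for i, g in enumerate(_STATE_ORDER)}, grid=grid)


def _set_to_state(gs: GradientSet) -> np.ndarray:
    gs.require(*_STATE_ORDER)
    return np.vstack([gs[g] for g in _STATE_ORDER])


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def normalizers(inputs: GradientSet, params: ModelParams) -> Dict[str, float]:
    """Per-gene synthesis normalizers omega_A = 1 / max_x P_A(x, 0).

    The initial state has the maternal Hb profile as Hb and all other gap
    genes at zero; a gene whose potential vanishes everywhere at t = 0
    cannot be activated and raises :class:`DegenerateCueError`.
    """
    ctx = _Context(inputs, params)
    pot0 = ctx.potentials(_initial_state(inputs))
    omega = {}
    for i, gene in enumerate(_STATE_ORDER):
        peak = float(pot0[i].max())
        if peak <= 0:
            if gene in params.null_genes:
                omega[gene] = 0.0
                continue
            raise DegenerateCueError(
                f"synthesis potential of {gene} is zero everywhere at t=0"
            )
        omega[gene] = 1.0 / peak
    return omega


def _require_omega(params: ModelParams) -> np.ndarray:
    if params.omega is None:
        raise ConfigError("omega not set; call normalizers() first "
                          "(or use run_simulation, which sets it)")
    return np.array([params.omega[g] for g in _STATE_ORDER])


def synthesis_field(state: GradientSet, inputs: GradientSet,
                    params: ModelParams, gene: str) -> np.ndarray:
    """Synthesis term alpha * omega_A * P_A(x) for one gene (nM/min)."""
    if gene not in _STATE_ORDER:
        raise KeyError(f"unknown gap gene {gene!r}")
    omega = _require_omega(params)
    ctx = _Context(inputs, params)
    pot = ctx.potentials(_set_to_state(state))
    i = _STATE_ORDER.index(gene)
    return params.alpha * omega[i] * pot[i]


def diffuse(values: np.ndarray, D: float, dt: float, dx: float) -> np.ndarray:
    """One diffusion substep: Gaussian filter of width sigma = sqrt(2 D dt).

    The filter acts along the last axis with reflecting boundaries (the
    method-of-images kernel for a no-flux domain), so interior mass is
    conserved; D = 0 is the identity.
    """
    if D < 0:
        raise ConfigError("D must be non-negative")
    values = np.asarray(values, dtype=float)
    sigma = np.sqrt(2.0 * D * dt) / dx
    if sigma == 0:
        return values.copy()
    return gaussian_filter1d(values, sigma, axis=-1, mode="reflect")


def _diffusion_matrix(n: int, D: float, dt: float, dx: float) -> Optional[np.ndarray]:
    """Dense one-step diffusion operator (None when D = 0)."""
    sigma = np.sqrt(2.0 * D * dt) / dx
    if sigma == 0:
        return None
    return gaussian_filter1d(np.eye(n), sigma, axis=0, mode="reflect")


def _check_stability(params: ModelParams, dt: float) -> None:
    if dt <= 0:
        raise ConfigError("dt must be positive")
    if dt * params.beta >= 1.0:
        raise ConfigError(
            f"explicit Euler unstable: dt*beta = {dt * params.beta:.3g} >= 1"
        )


def _step(state: np.ndarray, ctx: _Context, alpha_omega: np.ndarray,
          dt: float, dmat: Optional[np.ndarray]) -> np.ndarray:
    params = ctx.params
    synth = alpha_omega[:, None] * ctx.potentials(state)
    new = state + dt * (synth - params.beta * state)
    if dmat is not None:
        new = new @ dmat.T
    if new.max() > params.C_max * (1 + 1e-12):
        warnings.warn("concentration clipped at C_max", RuntimeWarning, stacklevel=2)
    return np.clip(new, 0.0, params.C_max)


def euler_step(state: GradientSet, inputs: GradientSet, params: ModelParams,
               dt: float = 2.2) -> GradientSet:
    """One explicit Euler step (synthesis/decay, then diffusion, then clipping)."""
    _check_stability(params, dt)
    omega = _require_omega(params)
    ctx = _Context(inputs, params)
    dmat = _diffusion_matrix(inputs.grid.n_points, params.D, dt, inputs.grid.dx)
    new = _step(_set_to_state(state), ctx, params.alpha * omega, dt, dmat)
    return _state_to_set(new, inputs.grid)


def run_simulation(inputs: GradientSet, params: ModelParams,
                   n_steps: int = 40, dt: float = 2.2) -> Trajectory:
    """Integrate the four-gene model from the maternal initial condition.

    ``inputs`` must contain Bcd, Hb_mat and Tll (Cad is derived from Bcd if
    absent); the initial gap state is {Hb: maternal Hb, Kr/Kni/Gt: 0}.  The
    maternal profiles are constant in time.  If ``params.omega`` is unset the
    normalizers are computed from these inputs first.  Returns a trajectory
    of ``n_steps + 1`` states (including t = 0).
    """
    _check_stability(params, dt)
    if params.omega is None:
        params = params.with_omega(normalizers(inputs, params))
    omega = _require_omega(params)
    ctx = _Context(inputs, params)
    dmat = _diffusion_matrix(inputs.grid.n_points, params.D, dt, inputs.grid.dx)
    alpha_omega = params.alpha * omega

    state = _initial_state(inputs)
    if "Hb" in params.null_genes:
        state[0] = 0.0
    times = [0.0]
    states = [_state_to_set(state, inputs.grid)]
    for k in range(n_steps):
        state = _step(state, ctx, alpha_omega, dt, dmat)
        times.append((k + 1) * dt)
        states.append(_state_to_set(state, inputs.grid))
    return Trajectory(np.array(times), states)


def final_state(inputs: GradientSet, params: ModelParams,
                n_steps: int = 40, dt: float = 2.2) -> np.ndarray:
    """Fast path: final (4, n) state [Hb, Kr, Kni, Gt] without trajectory records.

    Used heavily by the fitter; identical arithmetic to :func:`run_simulation`.
    """
    _check_stability(params, dt)
    if params.omega is None:
        params = params.with_omega(normalizers(inputs, params))
    omega = _require_omega(params)
    ctx = _Context(inputs, params)
    dmat = _diffusion_matrix(inputs.grid.n_points, params.D, dt, inputs.grid.dx)
    alpha_omega = params.alpha * omega
    state = _initial_state(inputs)
    if "Hb" in params.null_genes:
        state[0] = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(n_steps):
            state = _step(state, ctx, alpha_omega, dt, dmat)
    return state
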