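"""Metropolis-Hastings fitting of the dynamic model to gap-gene profiles.

The objective of a parameter point is the worst (minimum) of the four
per-gene Pearson correlations between the simulated final state and the
target profiles, each computed only within that gene's fitting range
(defaults: Hb 30-70, Gt 10-90, Kr 20-80, Kni 40-90 % e.l.).  Open
parameters live on discrete grids (100 values per parameter; the number of
binding sites on the integers 1-20); a proposal moves one uniformly chosen
open parameter by +-1 grid index (reflecting at the bounds) and is accepted
when ``exp((r_new - r_old) / T) > U`` with U uniform on [0, 1), so
improvements are always taken.  Each seed point starts a fresh chain from a
random grid position; the best state visited by each chain is recorded.

Quality solutions additionally require every gap gene to reach at least
half of the maximal concentration (25 of 50 nM) - the relative shape, not
the amplitude ratio between genes, is what the correlation rewards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import GAP_GENES, GradientSet
from .dynamics import ModelParams, final_state

__all__ = [
    "DEFAULT_FIT_RANGES",
    "DEFAULT_GRIDS",
    "FitTargets",
    "ModelVariant",
    "Solution",
    "objective",
    "per_gene_correlations",
    "propose",
    "accept",
    "metropolis_fit",
    "filter_solutions",
]

#: per-gene fitting ranges in % e.l.
DEFAULT_FIT_RANGES: Dict[str, Tuple[float, float]] = {
    "Hb": (30.0, 70.0),
    "Gt": (10.0, 90.0),
    "Kr": (20.0, 80.0),
    "Kni": (40.0, 90.0),
}

#: grid state order used inside the simulator
_STATE_ORDER = ("Hb", "Kr", "Kni", "Gt")


def _default_grids() -> Dict[str, np.ndarray]:
    return {
        # affinities: log-uniform over five decades, nM^-1
        "K": np.logspace(-3, 2, 100),
        "K1": np.logspace(-3, 2, 100),
        "K2": np.logspace(-3, 2, 100),
        "C": np.linspace(1.0, 20.0, 100),
        "N": np.arange(1, 21, dtype=float),
        "D": np.linspace(0.0, 30.0, 100),
        # single rate parameter: alpha = rate * C_max, beta = rate;
        # upper bound keeps explicit Euler stable at dt = 2.2 min
        "rate": np.linspace(0.02, 0.45, 100),
    }


DEFAULT_GRIDS = _default_grids()

_OPENABLE = ("K", "K1", "K2", "C", "N", "D", "rate")


@dataclass(frozen=True)
class FitTargets:
    """Target gap profiles plus per-gene fitting ranges (% e.l.)."""

    profiles: GradientSet
    ranges: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FIT_RANGES))

    def __post_init__(self) -> None:
        self.profiles.require(*GAP_GENES)
        for gene, (lo, hi) in self.ranges.items():
            if not (0 <= lo < hi <= 100):
                raise ValueError(f"bad fitting range for {gene}: ({lo}, {hi})")

    def masks(self) -> Dict[str, np.ndarray]:
        grid = self.profiles.grid
        return {g: grid.mask(*self.ranges[g]) for g in GAP_GENES}


@dataclass(frozen=True)
class ModelVariant:
    """Which parameters are open to fitting, on what grids, and the fixed rest.

    ``open_params`` maps parameter names (subset of K, K1, K2, C, N, D,
    rate) to their value grids; ``fixed`` pins the remaining ones.  K1/K2
    that are neither open nor fixed follow the global K (symmetric
    repression on that toggle edge).
    """

    name: str
    open_params: Dict[str, np.ndarray]
    fixed: Dict[str, float] = field(default_factory=dict)
    kr_rep_K: Optional[float] = None
    #: which parameter an unspecified K2 follows: "K" (global) or "K1" (the
    #: single node-specific toggle affinity serving both repressor edges)
    k2_follows: str = "K"

    def __post_init__(self) -> None:
        if not 1 <= len(self.open_params) <= 10:
            raise ValueError("variants support 1..10 open parameters")
        for name in list(self.open_params) + list(self.fixed):
            if name not in _OPENABLE:
                raise ValueError(f"unknown parameter {name!r}")
        overlap = set(self.open_params) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both open and fixed: {sorted(overlap)}")
        if "K" not in self.open_params and "K" not in self.fixed:
            raise ValueError("global affinity K must be open or fixed")
        if "rate" not in self.open_params and "rate" not in self.fixed:
            raise ValueError("rate (alpha=beta) must be open or fixed")

    @property
    def param_names(self) -> Tuple[str, ...]:
        return tuple(self.open_params)

    @property
    def grid_sizes(self) -> Tuple[int, ...]:
        return tuple(len(g) for g in self.open_params.values())

    def values_at(self, indices: Sequence[int]) -> Dict[str, float]:
        return {name: float(grid[i])
                for (name, grid), i in zip(self.open_params.items(), indices)}

    def to_model_params(self, indices: Sequence[int]) -> ModelParams:
        """Materialize a :class:`ModelParams` from grid indices."""
        values = dict(self.fixed)
        values.update(self.values_at(indices))
        rate = values.pop("rate")
        n = int(round(values.pop("N", 5)))
        k2 = values.get("K2")
        if k2 is None and self.k2_follows == "K1":
            k2 = values.get("K1")
        return ModelParams.coupled(
            rate,
            K=values["K"],
            K1=values.get("K1"),
            K2=k2,
            C=values.get("C", 5.0),
            N=n,
            D=values.get("D", 0.0),
            kr_rep_K=self.kr_rep_K,
        )

    # -- the two variants exercised throughout ---------------------------
    @classmethod
    def b7(cls, grids: Optional[Dict[str, np.ndarray]] = None) -> "ModelVariant":
        """7 open parameters: K, K1, K2, C, N, D, rate (the "B-7" design)."""
        grids = grids or DEFAULT_GRIDS
        return cls("B-7", {k: np.asarray(grids[k], float)
                           for k in ("K", "K1", "K2", "C", "N", "D", "rate")})

    @classmethod
    def b4(cls, N: int = 5, grids: Optional[Dict[str, np.ndarray]] = None) -> "ModelVariant":
        """4 open parameters (K, K1, C, rate): no diffusion, fixed site count,
        one node-specific affinity (K2 follows the global K)."""
        grids = grids or DEFAULT_GRIDS
        return cls("B-4", {k: np.asarray(grids[k], float)
                           for k in ("K", "K1", "C", "rate")},
                   fixed={"D": 0.0, "N": float(N)}, k2_follows="K1")


@dataclass
class Solution:
    """One fitted parameter point with its quality scores."""

    variant: str
    indices: Tuple[int, ...]
    params: Dict[str, float]
    r: float
    r_per_gene: Dict[str, float]
    max_conc: Dict[str, float]
    seed_index: int

    @property
    def amplitude_ok(self) -> bool:
        return all(v >= 25.0 for v in self.max_conc.values())


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return -1.0     # zero-variance output: worst score
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def per_gene_correlations(model_final, targets: FitTargets) -> Dict[str, float]:
    """Pearson r per gap gene within its fitting range.

    ``model_final`` may be a GradientSet or the internal (4, n) state array.
    """
    if isinstance(model_final, GradientSet):
        state = {g: model_final[g] for g in GAP_GENES}
    else:
        state = {g: model_final[i] for i, g in enumerate(_STATE_ORDER)}
    masks = targets.masks()
    return {g: _pearson(state[g][masks[g]], targets.profiles[g][masks[g]])
            for g in GAP_GENES}


def objective(model_final, targets: FitTargets) -> float:
    """min over the four genes of the in-range Pearson correlation."""
    return min(per_gene_correlations(model_final, targets).values())


# ---------------------------------------------------------------------------
# Metropolis kernel
# ---------------------------------------------------------------------------

def propose(current: Sequence[int], variant: ModelVariant,
            rng: np.random.Generator) -> Tuple[int, ...]:
    """Move one uniformly chosen open parameter by +-1 index, reflecting at bounds."""
    current = tuple(current)
    which = int(rng.integers(len(current)))
    step = 1 if rng.integers(2) else -1
    size = variant.grid_sizes[which]
    new = current[which] + step
    if new < 0:
        new = 1 if size > 1 else 0
    elif new >= size:
        new = size - 2 if size > 1 else size - 1
    out = list(current)
    out[which] = new
    return tuple(out)


def accept(r_current: float, r_proposed: float, temperature: float, u: float) -> bool:
    """Metropolis rule: accept iff exp((r_proposed - r_current)/T) > U."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if r_proposed >= r_current:
        return True
    return float(np.exp((r_proposed - r_current) / temperature)) > u


def _evaluate(indices: Tuple[int, ...], variant: ModelVariant,
              inputs: GradientSet, targets: FitTargets,
              n_euler_steps: int, dt: float):
    """Simulate one parameter point; simulation failure scores -1."""
    try:
        params = variant.to_model_params(indices)
        state = final_state(inputs, params, n_steps=n_euler_steps, dt=dt)
    except Exception:
        nan = {g: float("nan") for g in GAP_GENES}
        return -1.0, {g: -1.0 for g in GAP_GENES}, nan
    r_genes = per_gene_correlations(state, targets)
    max_conc = {g: float(state[i].max()) for i, g in enumerate(_STATE_ORDER)}
    return min(r_genes.values()), r_genes, max_conc


def metropolis_fit(targets: FitTargets, variant: ModelVariant,
                   inputs: GradientSet, n_seeds: int = 50, n_steps: int = 500,
                   master_seed: int = 0, temperature: float = 0.05,
                   n_euler_steps: int = 40, dt: float = 2.2,
                   initial_indices: Optional[Sequence[Sequence[int]]] = None,
                   progress: bool = False) -> List[Solution]:
    """Run independent Metropolis chains and return the best state of each.

    Every seed point starts from a uniformly random grid position (unless
    ``initial_indices`` pins the starts) and runs ``n_steps``
    propose/evaluate/accept iterations; each evaluation integrates the full
    dynamic model from the maternal initial condition and scores the final
    state.  With ``n_steps = 0`` only the seed points are evaluated.
    Identical ``master_seed`` reproduces the identical solution list.
    """
    root = np.random.default_rng(master_seed)
    seed_rngs = [np.random.default_rng(s) for s in
                 root.integers(0, 2**31 - 1, size=n_seeds)]
    sizes = variant.grid_sizes
    solutions: List[Solution] = []
    iterator = range(n_seeds)
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc=f"fit {variant.name}")
        except ImportError:
            pass
    for seed_idx in iterator:
        rng = seed_rngs[seed_idx]
        if initial_indices is not None:
            current = tuple(int(i) for i in initial_indices[seed_idx])
        else:
            current = tuple(int(rng.integers(s)) for s in sizes)
        r_cur, r_genes, max_conc = _evaluate(current, variant, inputs, targets,
                                             n_euler_steps, dt)
        best = (r_cur, current, r_genes, max_conc)
        for _ in range(n_steps):
            proposed = propose(current, variant, rng)
            r_prop, rg_prop, mc_prop = _evaluate(proposed, variant, inputs,
                                                 targets, n_euler_steps, dt)
            if accept(r_cur, r_prop, temperature, float(rng.random())):
                current, r_cur = proposed, r_prop
                if r_prop > best[0]:
                    best = (r_prop, proposed, rg_prop, mc_prop)
        solutions.append(Solution(
            variant=variant.name,
            indices=best[1],
            params=variant.values_at(best[1]) | dict(variant.fixed),
            r=best[0],
            r_per_gene=best[2],
            max_conc=best[3],
            seed_index=seed_idx,
        ))
    return solutions


def filter_solutions(solutions: Sequence[Solution], r_threshold: float = 0.7,
                     amplitude_threshold: float = 25.0) -> List[Solution]:
    """Quality filter: r strictly above threshold and every gene's peak at
    least ``amplitude_threshold`` nM (default half of C_max)."""
    out = []
    for sol in solutions:
        if sol.r > r_threshold and all(
                np.isfinite(v) and v >= amplitude_threshold
                for v in sol.max_conc.values()):
            out.append(sol)
    return out
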