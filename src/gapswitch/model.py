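"""Model / results interface over the fitting machinery.

:class:`GapGeneModel` bundles the maternal inputs, the target gap profiles
(with their fitting ranges) and a model variant; :meth:`GapGeneModel.fit`
runs the Metropolis-Hastings search and returns a
:class:`GapGeneFitResults` carrying the solution ensemble, the best
parameter point, per-gene correlations, a text ``summary()``, and forward /
mutant simulation from the fitted parameters.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GAP_GENES, GradientSet
from .dynamics import ModelParams, Trajectory, run_simulation
from .fitting import (DEFAULT_FIT_RANGES, FitTargets, ModelVariant, Solution,
                      filter_solutions, metropolis_fit, objective)
from .mutants import MutantSpec, mutant_report, simulate_mutant

__all__ = ["GapGeneModel", "GapGeneFitResults"]


class GapGeneModel:
    """Dynamic gap-gene model bound to maternal inputs and target profiles.

    Parameters
    ----------
    targets : GradientSet or FitTargets
        Gap-gene profiles to fit (cycle-14.4-like final patterns); a plain
        GradientSet gets the default per-gene fitting ranges.
    inputs : GradientSet
        Maternal profiles Bcd, Hb_mat, Tll (Cad derived if absent).
    variant : ModelVariant, optional
        Which parameters are open; defaults to the 7-parameter B-7 design.
    n_euler_steps, dt :
        Integration length (default 40 steps of 2.2 min).
    temperature :
        Metropolis acceptance temperature on the correlation scale.
    """

    def __init__(self, targets, inputs: GradientSet,
                 variant: Optional[ModelVariant] = None,
                 n_euler_steps: int = 40, dt: float = 2.2,
                 temperature: float = 0.05):
        self.targets = targets if isinstance(targets, FitTargets) else FitTargets(targets)
        self.inputs = inputs
        self.variant = variant or ModelVariant.b7()
        self.n_euler_steps = n_euler_steps
        self.dt = dt
        self.temperature = temperature

    @classmethod
    def from_dataframe(cls, targets_frame: pd.DataFrame,
                       inputs_frame: pd.DataFrame, **kwargs) -> "GapGeneModel":
        """Build from tidy (gene, x_percent_el, conc_nM) tables."""
        return cls(GradientSet.from_frame(targets_frame),
                   GradientSet.from_frame(inputs_frame), **kwargs)

    # -- evaluation -------------------------------------------------------
    def simulate(self, params: ModelParams) -> Trajectory:
        """Forward-simulate the dynamic model at explicit parameters."""
        return run_simulation(self.inputs, params,
                              n_steps=self.n_euler_steps, dt=self.dt)

    def score(self, params: ModelParams) -> float:
        """Objective (min-over-genes in-range Pearson r) at explicit parameters."""
        return objective(self.simulate(params).final, self.targets)

    def fit(self, n_seeds: int = 50, n_steps: int = 500,
            seed: int = 0, progress: bool = False,
            initial_indices: Optional[Sequence[Sequence[int]]] = None
            ) -> "GapGeneFitResults":
        """Metropolis-Hastings search; returns the fitted results object."""
        solutions = metropolis_fit(
            self.targets, self.variant, self.inputs,
            n_seeds=n_seeds, n_steps=n_steps, master_seed=seed,
            temperature=self.temperature, n_euler_steps=self.n_euler_steps,
            dt=self.dt, initial_indices=initial_indices, progress=progress)
        return GapGeneFitResults(self, solutions)


class GapGeneFitResults:
    """Solution ensemble returned by :meth:`GapGeneModel.fit`."""

    def __init__(self, model: GapGeneModel, solutions: List[Solution]):
        self.model = model
        self.solutions = list(solutions)
        if not self.solutions:
            raise ValueError("no solutions recorded")
        self.best: Solution = max(self.solutions, key=lambda s: s.r)

    # -- estimates --------------------------------------------------------
    @property
    def r(self) -> float:
        """Best min-over-genes Pearson correlation found."""
        return self.best.r

    @property
    def r_per_gene(self) -> Dict[str, float]:
        return dict(self.best.r_per_gene)

    @property
    def params(self) -> ModelParams:
        """ModelParams of the best solution."""
        return self.model.variant.to_model_params(self.best.indices)

    def filter(self, r_threshold: float = 0.7,
               amplitude_threshold: float = 25.0) -> List[Solution]:
        """Quality solutions (r above threshold, all genes >= amplitude)."""
        return filter_solutions(self.solutions, r_threshold, amplitude_threshold)

    def to_frame(self) -> pd.DataFrame:
        """One row per chain: parameters, objective, per-gene r and peaks."""
        rows = []
        for sol in self.solutions:
            row = {"seed_index": sol.seed_index, "r": sol.r}
            row.update({f"param_{k}": v for k, v in sol.params.items()})
            row.update({f"r_{g}": sol.r_per_gene[g] for g in GAP_GENES})
            row.update({f"max_{g}": sol.max_conc[g] for g in GAP_GENES})
            rows.append(row)
        return pd.DataFrame(rows).sort_values("r", ascending=False,
                                              ignore_index=True)

    # -- simulation from the fit ------------------------------------------
    def simulate(self, mutant: Optional[MutantSpec] = None) -> Trajectory:
        """Forward-simulate the best solution, optionally under a mutant spec."""
        if mutant is None:
            return self.model.simulate(self.params)
        return simulate_mutant(self.model.inputs, self.params, mutant,
                               n_steps=self.model.n_euler_steps, dt=self.model.dt)

    def mutant_report(self, mutant: MutantSpec) -> Dict[str, dict]:
        """Qualitative wild-type vs mutant comparison for the best solution."""
        return mutant_report(self.simulate(), self.simulate(mutant))

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary."""
        variant = self.model.variant
        n_quality = len(self.filter())
        lines = [
            "Gap-gene network fit (Metropolis-Hastings)",
            "=" * 44,
            f"variant:            {variant.name} "
            f"({len(variant.open_params)} open parameters)",
            f"chains:             {len(self.solutions)}",
            f"best objective r:   {self.r:.4f}  (min over genes, in-range Pearson)",
            f"quality solutions:  {n_quality}  (r > 0.7, all genes >= 25 nM)",
            "",
            "best solution:",
        ]
        for name, value in self.best.params.items():
            lines.append(f"  {name:<6} = {value:.6g}")
        lines.append("")
        lines.append("per-gene correlation / peak concentration (best solution):")
        for gene in GAP_GENES:
            lines.append(f"  {gene:<4} r = {self.best.r_per_gene[gene]:+.4f}   "
                         f"max = {self.best.max_conc[gene]:6.2f} nM")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<GapGeneFitResults variant={self.model.variant.name} "
                f"chains={len(self.solutions)} best_r={self.r:.3f}>")

    def plot_profiles(self, ax=None):
        """Plot target vs fitted final profiles (matplotlib axes)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        x = self.model.inputs.grid.x
        final = self.simulate().final
        colors = {"Hb": "tab:blue", "Kr": "tab:green",
                  "Kni": "tab:red", "Gt": "tab:purple"}
        for gene in GAP_GENES:
            ax.plot(x, self.model.targets.profiles[gene], ":",
                    color=colors[gene], label=f"{gene} target")
            ax.plot(x, final[gene], "-", color=colors[gene], label=f"{gene} model")
        ax.set_xlabel("position (% embryo length, anterior = 0)")
        ax.set_ylabel("concentration (nM)")
        ax.legend(ncol=4, fontsize=8)
        return ax
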