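"""Synthetic maternal gradients and wild-type gap-gene target profiles.

Stand-in for quantitative embryo expression data (FlyEx-style tables): an
anterior-high exponential Bicoid gradient, a sigmoidal anterior maternal
Hunchback profile, a posterior terminal Tailless gradient, and four
wild-type gap patterns, all on the shared axis grid with optional
multiplicative lognormal noise.  Everything is deterministic given the seed.

Two target modes exist:

* ``model-forward`` runs the dynamic model at known parameters and returns
  its final state - the assumption-free ground truth for parameter-recovery
  tests;
* ``stylized`` draws the canonical wild-type geography directly (anterior Hb
  plateau, central Kr domain, abdominal Kni stripe near 65 % e.l., anterior
  + posterior Gt stripes) as Gaussian/sigmoid mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .core import C_MAX, AxisGrid, GradientSet

__all__ = ["SynthConfig", "gen_maternal_inputs", "gen_targets", "swap_genes"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic expression profiles (concentrations nM,
    positions % e.l.)."""

    grid: AxisGrid = field(default_factory=AxisGrid)
    # maternal inputs
    bcd_amplitude: float = 50.0
    bcd_length_scale: float = 20.0          # exponential decay length, % e.l.
    hb_amplitude: float = 50.0
    hb_midpoint: float = 47.0               # sigmoid half-max position
    hb_width: float = 3.0
    tll_amplitude: float = 50.0
    tll_onset: float = 80.0                 # posterior sigmoid half-max
    tll_width: float = 3.0
    # gap targets
    mode: str = "model-forward"             # or "stylized"
    stylized_domains: Dict[str, Tuple] = field(default_factory=lambda: dict(_STYLIZED))
    noise_sigma: float = 0.0                # lognormal sigma; 0.1 emulates embryo noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("model-forward", "stylized"):
            raise ValueError(f"unknown target mode {self.mode!r}")
        for name in ("bcd_amplitude", "hb_amplitude", "tll_amplitude"):
            amp = getattr(self, name)
            if not 0 < amp <= C_MAX:
                raise ValueError(f"{name} must be in (0, {C_MAX}] nM")
        if self.bcd_length_scale <= 0 or self.hb_width <= 0 or self.tll_width <= 0:
            raise ValueError("length scales must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


# stylized wild-type geography: per gene a list of (kind, center, width, amplitude)
_STYLIZED = {
    "Hb": (("sigmoid-", 45.0, 4.0, 45.0),),          # anterior plateau ending ~45 % e.l.
    "Kr": (("gauss", 50.0, 8.0, 45.0),),             # central domain ~40-60 % e.l.
    "Kni": (("gauss", 65.0, 5.0, 40.0),),            # abdominal stripe ~60-75 % e.l.
    "Gt": (("gauss", 20.0, 6.0, 35.0),               # anterior stripe
           ("gauss", 80.0, 6.0, 35.0)),              # posterior stripe
}


def _sigmoid(x: np.ndarray, midpoint: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp((x - midpoint) / width))


def gen_maternal_inputs(config: SynthConfig) -> GradientSet:
    """Maternal input gradients: Bcd (exponential), Hb_mat and Tll (sigmoids).

    Bcd is anterior-high and strictly decreasing; Tll is posterior-high with
    half-max at ``tll_onset``.  Cad is not generated here - it is derived
    from Bcd by the cue model and then held fixed.
    """
    x = config.grid.x
    bcd = config.bcd_amplitude * np.exp(-x / config.bcd_length_scale)
    hb_mat = config.hb_amplitude * _sigmoid(x, config.hb_midpoint, config.hb_width)
    tll = config.tll_amplitude * (1.0 - _sigmoid(x, config.tll_onset, config.tll_width))
    return GradientSet({"Bcd": bcd, "Hb_mat": hb_mat, "Tll": tll}, grid=config.grid)


def _stylized_profile(x: np.ndarray, components) -> np.ndarray:
    out = np.zeros_like(x)
    for kind, center, width, amplitude in components:
        if kind == "gauss":
            out = out + amplitude * np.exp(-0.5 * ((x - center) / width) ** 2)
        elif kind == "sigmoid-":    # anterior-high plateau falling at `center`
            out = out + amplitude * _sigmoid(x, center, width)
        elif kind == "sigmoid+":    # posterior-high
            out = out + amplitude * (1.0 - _sigmoid(x, center, width))
        else:
            raise ValueError(f"unknown component kind {kind!r}")
    return out


def gen_targets(config: SynthConfig, params=None) -> GradientSet:
    """Wild-type gap-gene target profiles (Hb, Kr, Kni, Gt).

    In ``model-forward`` mode the final state of the dynamic model at
    ``params`` is used (required argument); in ``stylized`` mode the
    configured domain mixtures are drawn directly.  Multiplicative lognormal
    noise of sigma ``noise_sigma`` is then applied and values are clipped to
    [0, C_max].
    """
    x = config.grid.x
    if config.mode == "model-forward":
        if params is None:
            raise ValueError("model-forward targets require model parameters")
        from .dynamics import run_simulation
        inputs = gen_maternal_inputs(config)
        final = run_simulation(inputs, params).final
        targets = {gene: final[gene] for gene in ("Hb", "Kr", "Kni", "Gt")}
    else:
        targets = {gene: _stylized_profile(x, comps)
                   for gene, comps in config.stylized_domains.items()}

    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        for gene in targets:
            noise = rng.lognormal(mean=0.0, sigma=config.noise_sigma, size=x.shape)
            targets[gene] = targets[gene] * noise
    targets = {g: np.clip(v, 0.0, C_MAX) for g, v in targets.items()}
    return GradientSet(targets, grid=config.grid)


def swap_genes(targets: GradientSet, gene_a: str, gene_b: str) -> GradientSet:
    """Exchange two gene profiles (the deliberately-incorrect-data control)."""
    targets.require(gene_a, gene_b)
    out = targets.copy()
    out.set(gene_a, targets[gene_b])
    out.set(gene_b, targets[gene_a])
    return out
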