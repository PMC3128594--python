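"""Packaged best-fit wild-type solution.

One curated parameter point of the 7-parameter (B-7) model design, selected
for realistic parameter values, a wild-type gap geography on the default
synthetic maternal inputs (anterior Hb, central Kr, abdominal Kni stripe,
anterior + posterior Gt stripes) and qualitative agreement across the
mutant panel.  It also serves as the ground-truth generator for
model-forward synthetic targets in parameter-recovery tests.

All values sit on the default fitting grids.
"""

from __future__ import annotations

from typing import Dict

from .core import GradientSet
from .dynamics import ModelParams
from .synthetic import SynthConfig, gen_maternal_inputs

__all__ = ["reference_solution", "reference_params", "reference_inputs",
           "REFERENCE_GRID_INDICES"]

#: grid indices of the packaged solution on the default B-7 grids
#: (order: K, K1, K2, C, N, D, rate)
REFERENCE_GRID_INDICES: Dict[str, int] = {
    "K": 23,    # global affinity 0.015 nM^-1 (weak, shared by 12 edges)
    "K1": 50,   # Hb -| Kni repressor array, 0.34 nM^-1
    "K2": 56,   # Kr -| Gt repressor array, 0.67 nM^-1
    "C": 8,     # cooperativity fold 2.5
    "N": 5,     # 6 sites per array
    "D": 16,    # 4.8 um^2/min
    "rate": 9,  # beta = 0.059 /min, alpha = beta * C_max
}


def reference_solution() -> Dict[str, float]:
    """Parameter values of the packaged best-fit solution."""
    from .fitting import DEFAULT_GRIDS
    return {name: float(DEFAULT_GRIDS[name][idx])
            for name, idx in REFERENCE_GRID_INDICES.items()}

def reference_params() -> ModelParams:
    """The packaged solution as :class:`ModelParams` (omega unset)."""
    values = reference_solution()
    return ModelParams.coupled(
        values["rate"], K=values["K"], K1=values["K1"], K2=values["K2"],
        C=values["C"], N=int(round(values["N"])), D=values["D"])


def reference_inputs(seed: int = 0) -> GradientSet:
    """Default synthetic maternal inputs used with the packaged solution."""
    return gen_maternal_inputs(SynthConfig(seed=seed))
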