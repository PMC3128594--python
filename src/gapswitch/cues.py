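"""Steady-state maternal positional cues for Caudal and the four gap genes.

Each cue is the x-dependent synthesis potential a gap gene receives from the
maternal system, expressed through fractional site occupancies:

* Hunchback (anterior domain): Bcd AND Hb autoactivation,
  ``P = p_Bcd * p_Hb``;
* Caudal: translational repression by Bcd, ``P = 1 - p_Bcd``, computed once
  and then treated as a stable maternal input;
* Kruppel: dual regulation by Hb, ``P = p_Hb_act * (1 - p_Hb_rep)``
  (band-pass in Hb concentration);
* Knirps: Bcd activation with repression by Hb through a separate
  repressor-specific array, ``P = p_Bcd * (1 - p_HbR)``;
* Giant: Bcd OR Cad activation with Tll repression,
  ``P = (1 - (1 - p_Bcd)(1 - p_Cad)) * (1 - p_Tll)``.

Every Bcd-activator edge shares one global Bcd site array (the model assumes
identical Bcd site arrays on all Bcd-regulated enhancers); Hb as activator or
dual regulator shares the Hb array, while Hb as a dedicated repressor (on
kni) may use a different array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .core import GridMismatchError, Profile
from .occupancy import SiteArray, integrate_and, integrate_or, site_occupancy

__all__ = [
    "CueModel",
    "cue_hb",
    "cue_cad",
    "cue_kr",
    "cue_kni",
    "cue_gt",
]


@dataclass
class CueModel:
    """Named site arrays for one gap gene's maternal inputs.

    ``edges`` maps regulator labels ("Bcd", "Hb", "Hb_rep", "Cad", "Tll") to
    the :class:`SiteArray` used on that edge; ``logic`` records how activator
    inputs combine ("AND" or "OR").
    """

    gene: str
    edges: Dict[str, SiteArray] = field(default_factory=dict)
    logic: str = "AND"

    def array(self, regulator: str) -> SiteArray:
        try:
            return self.edges[regulator]
        except KeyError:
            raise KeyError(
                f"cue model for {self.gene!r} has no edge for regulator {regulator!r}"
            ) from None


def _values(profile, name: str, grid=None) -> np.ndarray:
    if isinstance(profile, Profile):
        if grid is not None and profile.grid != grid:
            raise GridMismatchError(f"{name} profile is on a different grid")
        return profile.values
    return np.asarray(profile, dtype=float)


def _common_grid(*profiles):
    grids = [p.grid for p in profiles if isinstance(p, Profile)]
    for g in grids[1:]:
        if g != grids[0]:
            raise GridMismatchError("cue inputs are on different grids")
    return grids[0] if grids else None


def cue_hb(bcd, hb, model: CueModel) -> np.ndarray:
    """Hunchback cue: Bcd AND Hb (both required)."""
    grid = _common_grid(bcd, hb)
    p_bcd = site_occupancy(_values(bcd, "Bcd", grid), model.array("Bcd"))
    p_hb = site_occupancy(_values(hb, "Hb", grid), model.array("Hb"))
    return integrate_and([p_bcd, p_hb])


def cue_cad(bcd, model: CueModel) -> np.ndarray:
    """Caudal cue: translational repression by Bcd, 1 - p_Bcd."""
    p_bcd = site_occupancy(_values(bcd, "Bcd"), model.array("Bcd"))
    return 1.0 - p_bcd


def cue_kr(hb, model: CueModel) -> np.ndarray:
    """Kruppel cue: dual Hb regulation, p_act * (1 - p_rep).

    By default activation and repression use the same Hb array (the dual
    regulator carries one set of constants), in which case the response is
    p(1-p): zero at both vanishing and saturating Hb, maximal where the
    array is half occupied.  A separate repressive array may be supplied
    under the "Hb_rep" edge.
    """
    hb_vals = _values(hb, "Hb")
    p_act = site_occupancy(hb_vals, model.array("Hb"))
    rep_array = model.edges.get("Hb_rep", model.array("Hb"))
    p_rep = site_occupancy(hb_vals, rep_array)
    return integrate_and([p_act], [p_rep])


def cue_kni(bcd, hb, model: CueModel) -> np.ndarray:
    """Knirps cue: Bcd activation, Hb repression via the repressor array."""
    grid = _common_grid(bcd, hb)
    p_bcd = site_occupancy(_values(bcd, "Bcd", grid), model.array("Bcd"))
    p_hbr = site_occupancy(_values(hb, "Hb", grid), model.array("Hb_rep"))
    return integrate_and([p_bcd], [p_hbr])


def cue_gt(bcd, cad, tll, model: CueModel) -> np.ndarray:
    """Giant cue: (Bcd OR Cad) activation with Tll repression."""
    grid = _common_grid(bcd, cad, tll)
    p_bcd = site_occupancy(_values(bcd, "Bcd", grid), model.array("Bcd"))
    p_cad = site_occupancy(_values(cad, "Cad", grid), model.array("Cad"))
    p_tll = site_occupancy(_values(tll, "Tll", grid), model.array("Tll"))
    return integrate_and([integrate_or([p_bcd, p_cad])], [p_tll])
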