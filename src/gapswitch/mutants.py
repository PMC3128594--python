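"""Reverse modeling of segmentation mutants.

A mutant is described declaratively: gap genes whose synthesis is nulled,
regulatory links removed from the network, maternal input profiles replaced
(e.g. uniform maternal Hb in a nanos background, zeroed Bcd), and dosage
multipliers (4 copies of bcd = 2x the wild-type gradient).  The perturbed
system is re-simulated with wild-type-fitted parameters, and qualitative
pattern metrics (peak position/amplitude, half-max boundaries, centroid,
presence) compare mutant and wild-type trajectories.

The terminal system enters the model only through Tll, so a torso null is
expressed as Tll = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

from .core import GAP_GENES, GradientSet
from .dynamics import (REGULATORY_LINKS, ConfigError, ModelParams, Trajectory,
                       normalizers, run_simulation)

__all__ = [
    "MutantSpec",
    "PatternMetrics",
    "apply_mutant",
    "simulate_mutant",
    "pattern_metrics",
    "mutant_report",
]

#: default amplitude below which a domain is called absent, nM (20 % of C_max)
PRESENCE_THRESHOLD = 10.0

#: minimal displacement for a shift call, % e.l. (one grid point)
SHIFT_THRESHOLD = 1.0


@dataclass(frozen=True)
class MutantSpec:
    """Declarative genetic perturbation.

    ``input_overrides`` maps input gene ids to replacement profiles; the
    special value ``("uniform", level)`` produces a flat profile at
    ``level`` nM.  ``dosage`` multiplies input amplitudes uniformly in x.
    """

    null_genes: FrozenSet[str] = frozenset()
    removed_links: FrozenSet[str] = frozenset()
    input_overrides: Dict[str, object] = field(default_factory=dict)
    dosage: Dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        bad = set(self.null_genes) - set(GAP_GENES)
        if bad:
            raise ConfigError(f"unknown null gene(s): {sorted(bad)}")
        bad = set(self.removed_links) - REGULATORY_LINKS
        if bad:
            raise ConfigError(f"unknown regulatory link(s): {sorted(bad)}")
        for gene, mult in self.dosage.items():
            if mult <= 0:
                raise ConfigError(f"dosage multiplier for {gene} must be > 0")

    @property
    def is_identity(self) -> bool:
        return not (self.null_genes or self.removed_links
                    or self.input_overrides or self.dosage)


def _null_links(gene: str) -> FrozenSet[str]:
    """Links emanating from a nulled gap gene (its protein is absent)."""
    prefix = f"{gene}->"
    rep_prefix = f"{gene}-|"
    return frozenset(l for l in REGULATORY_LINKS
                     if l.startswith(prefix) or l.startswith(rep_prefix))


def apply_mutant(inputs: GradientSet, params: ModelParams,
                 spec: MutantSpec) -> Tuple[GradientSet, ModelParams]:
    """Return perturbed copies of the inputs and parameters.

    The wild-type objects are untouched.  Nulling a gene forces its
    synthesis to zero and removes its outgoing regulatory links; removing a
    link zeroes the corresponding occupancy term (activators) or fixes the
    repression factor at one (repressors).  The per-gene normalizers
    ``omega`` are part of the wild-type solution: if unset they are computed
    from the *unperturbed* inputs before the perturbation is applied.
    """
    if params.omega is None:
        params = params.with_omega(normalizers(inputs, params))

    new_inputs = inputs.copy()
    for gene, override in spec.input_overrides.items():
        if gene not in inputs:
            raise ConfigError(f"override for unknown input gene {gene!r}")
        if isinstance(override, tuple) and len(override) == 2 and override[0] == "uniform":
            values = np.full(inputs.grid.n_points, float(override[1]))
        else:
            values = np.asarray(override, dtype=float)
        new_inputs.set(gene, values)
    for gene, mult in spec.dosage.items():
        if gene not in new_inputs:
            raise ConfigError(f"dosage for unknown input gene {gene!r}")
        new_inputs.set(gene, new_inputs[gene] * mult)

    removed = set(spec.removed_links)
    for gene in spec.null_genes:
        removed |= _null_links(gene)
    new_params = replace(
        params,
        disabled_links=params.disabled_links | frozenset(removed),
        null_genes=params.null_genes | frozenset(spec.null_genes),
    )
    return new_inputs, new_params


def simulate_mutant(inputs: GradientSet, params: ModelParams, spec: MutantSpec,
                    n_steps: int = 40, dt: float = 2.2) -> Trajectory:
    """Apply a mutant spec and re-run the simulation (wild-type omega kept)."""
    mut_inputs, mut_params = apply_mutant(inputs, params, spec)
    return run_simulation(mut_inputs, mut_params, n_steps=n_steps, dt=dt)


# ---------------------------------------------------------------------------
# pattern metrics
# ---------------------------------------------------------------------------

@dataclass
class DomainMetrics:
    """Metrics of one expression domain."""

    peak_position: float        # % e.l.
    peak_amplitude: float       # nM
    boundaries: Tuple[float, float]   # half-max crossings, % e.l.
    centroid: float             # amplitude-weighted mean position, % e.l.


@dataclass
class PatternMetrics:
    """Qualitative description of one expression profile."""

    present: bool
    peak_position: Optional[float]
    peak_amplitude: float
    boundaries: Optional[Tuple[float, float]]
    centroid: Optional[float]
    domains: List[DomainMetrics] = field(default_factory=list)

    @property
    def n_domains(self) -> int:
        return len(self.domains)


def _half_max_boundaries(x: np.ndarray, y: np.ndarray, lo: int, hi: int,
                         peak_idx: int, half: float) -> Tuple[float, float]:
    """Interpolated half-max crossings around a peak within [lo, hi]."""
    left = x[lo]
    for i in range(peak_idx, lo, -1):
        if y[i - 1] < half <= y[i]:
            frac = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = x[i - 1] + frac * (x[i] - x[i - 1])
            break
    right = x[hi]
    for i in range(peak_idx, hi):
        if y[i + 1] < half <= y[i]:
            frac = (y[i] - half) / (y[i] - y[i + 1])
            right = x[i] + frac * (x[i + 1] - x[i])
            break
    return (float(left), float(right))


def _split_domains(y: np.ndarray) -> List[Tuple[int, int]]:
    """Split a profile at interior minima below half of the global max."""
    half = y.max() / 2.0
    cuts = []
    for i in range(1, len(y) - 1):
        if y[i] < half and y[i] <= y[i - 1] and y[i] <= y[i + 1]:
            cuts.append(i)
    # merge adjacent cut points (plateaus of low signal)
    segments = []
    start = 0
    for c in cuts:
        if c > start:
            segments.append((start, c))
        start = c
    segments.append((start, len(y) - 1))
    return segments


def pattern_metrics(profile, presence_threshold: float = PRESENCE_THRESHOLD,
                    grid=None) -> PatternMetrics:
    """Peak/boundary/centroid metrics of a profile; multimodal profiles are
    split at minima below half of the global maximum and described per domain.
    """
    from .core import Profile
    if isinstance(profile, Profile):
        y, x = profile.values, profile.grid.x
    else:
        y = np.asarray(profile, dtype=float)
        x = grid.x if grid is not None else np.arange(y.size) * (100.0 / y.size)

    amp = float(y.max())
    if amp < presence_threshold or amp <= 0:
        return PatternMetrics(present=False, peak_position=None,
                              peak_amplitude=amp, boundaries=None, centroid=None)

    domains = []
    for lo, hi in _split_domains(y):
        seg = y[lo:hi + 1]
        seg_amp = float(seg.max())
        if seg_amp < presence_threshold:
            continue
        peak_idx = lo + int(np.argmax(seg))
        bounds = _half_max_boundaries(x, y, lo, hi, peak_idx, seg_amp / 2.0)
        weights = seg.sum()
        centroid = float((x[lo:hi + 1] * seg).sum() / weights) if weights > 0 else x[peak_idx]
        domains.append(DomainMetrics(
            peak_position=float(x[peak_idx]),
            peak_amplitude=seg_amp,
            boundaries=bounds,
            centroid=centroid,
        ))

    peak_idx = int(np.argmax(y))
    total = y.sum()
    return PatternMetrics(
        present=True,
        peak_position=float(x[peak_idx]),
        peak_amplitude=amp,
        boundaries=_half_max_boundaries(x, y, 0, len(y) - 1, peak_idx, amp / 2.0),
        centroid=float((x * y).sum() / total),
        domains=domains,
    )


def mutant_report(wt: Trajectory, mut: Trajectory,
                  presence_threshold: float = PRESENCE_THRESHOLD,
                  shift_threshold: float = SHIFT_THRESHOLD) -> Dict[str, dict]:
    """Machine-readable per-gene comparison of mutant vs wild-type final states.

    For each gap gene: presence in both conditions, peak and centroid
    displacement (positive = posterior shift; a shift is only called when the
    displacement reaches ``shift_threshold`` % e.l.), and the mutant/wild-type
    amplitude ratio.
    """
    wt_final, mut_final = wt.final, mut.final
    grid = wt_final.grid
    report: Dict[str, dict] = {}
    for gene in GAP_GENES:
        m_wt = pattern_metrics(wt_final[gene], presence_threshold, grid=grid)
        m_mut = pattern_metrics(mut_final[gene], presence_threshold, grid=grid)
        peak_shift = centroid_shift = None
        direction = "none"
        if m_wt.present and m_mut.present:
            peak_shift = m_mut.peak_position - m_wt.peak_position
            centroid_shift = m_mut.centroid - m_wt.centroid
            if abs(peak_shift) >= shift_threshold:
                direction = "posterior" if peak_shift > 0 else "anterior"
        amp_ratio = (m_mut.peak_amplitude / m_wt.peak_amplitude
                     if m_wt.peak_amplitude > 0 else float("inf"))
        report[gene] = {
            "present_wt": m_wt.present,
            "present_mut": m_mut.present,
            "peak_wt": m_wt.peak_position,
            "peak_mut": m_mut.peak_position,
            "peak_shift": peak_shift,
            "centroid_shift": centroid_shift,
            "shift_direction": direction,
            "amplitude_wt": m_wt.peak_amplitude,
            "amplitude_mut": m_mut.peak_amplitude,
            "amplitude_ratio": amp_ratio,
            "n_domains_wt": m_wt.n_domains,
            "n_domains_mut": m_mut.n_domains,
        }
    return report
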