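"""Thermodynamic fractional site occupancy of homotypic binding-site arrays.

A regulatory input is modelled as an array of ``N`` equal, cooperating binding
sites with affinity ``K`` (per nM) and cooperativity fold ``C``.  The
statistical weight of having ``i`` sites bound at transcription-factor
concentration ``A`` is ``binom(N, i) * C**max(i - 1, 0) * (K * A)**i`` (each
molecule beyond the first contributes one factor of C: "chain" cooperativity),
and the probability that at least one site is occupied is ``p = 1 - 1/Z``
where ``Z`` sums the weights over all occupation numbers.

For ``C = 1, N = 1`` this reduces to the familiar hyperbola ``KA / (1 + KA)``.
Occupancies of independent arrays are combined with AND (product of
activations and of complements of repressions) or OR (complement of the
product of complements) logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SiteArray",
    "partition_function",
    "site_occupancy",
    "integrate_and",
    "integrate_or",
]

#: upper bound on the number of sites in one array (fitting-grid bound)
MAX_SITES = 20


@dataclass(frozen=True)
class SiteArray:
    """Homotypic binding-site array on one regulatory edge.

    Parameters
    ----------
    K : float
        Binding affinity, nM^-1 (concentrations live on a 0-50 nM scale).
    C : float
        Cooperativity fold, >= 1; multiplicative weight bonus per additional
        bound molecule.
    N : int
        Number of equal sites, 1..20.
    coop : str
        "chain" (default) scales the i-bound weight by C**(i-1);
        "pairwise" by C**binom(i, 2).
    """

    K: float
    C: float = 1.0
    N: int = 1
    coop: str = "chain"

    def __post_init__(self) -> None:
        if not (self.K > 0 and np.isfinite(self.K)):
            raise ValueError(f"affinity K must be positive and finite, got {self.K}")
        if self.C < 1:
            raise ValueError(f"cooperativity C must be >= 1, got {self.C}")
        if not (1 <= int(self.N) <= MAX_SITES) or int(self.N) != self.N:
            raise ValueError(f"site count N must be an integer in 1..{MAX_SITES}, got {self.N}")
        if self.coop not in ("chain", "pairwise"):
            raise ValueError(f"unknown cooperativity mode {self.coop!r}")
        object.__setattr__(self, "N", int(self.N))

    def weights(self) -> np.ndarray:
        """Polynomial coefficients a_i of Z(A) = sum_i a_i * A**i."""
        i = np.arange(self.N + 1)
        if self.coop == "chain":
            coop_exp = np.maximum(i - 1, 0)
        else:  # pairwise: one factor of C per bound pair
            coop_exp = i * (i - 1) // 2
        binom = np.array([math.comb(self.N, k) for k in i], dtype=float)
        return binom * self.C ** coop_exp * self.K ** i.astype(float)


def _check_conc(conc):
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0) or not np.all(np.isfinite(conc)):
        raise ValueError("concentration must be finite and non-negative")
    return conc


def partition_function(conc, array: SiteArray):
    """Statistical weight Z of the site array at concentration ``conc`` (nM).

    Z >= 1 always (the empty configuration has weight 1); accepts scalars or
    arrays and is evaluated by Horner's rule on the occupation-number
    polynomial.
    """
    conc = _check_conc(conc)
    coeffs = array.weights()
    z = np.full_like(conc, coeffs[-1]) if conc.ndim else coeffs[-1]
    for a_i in coeffs[-2::-1]:
        z = z * conc + a_i
    return z


def site_occupancy(conc, array: SiteArray):
    """Probability that at least one site of the array is occupied.

    ``p = 1 - 1/Z``; monotone nondecreasing in concentration, affinity,
    cooperativity and site count, with p -> 0 as conc -> 0 and p -> 1 as
    conc -> infinity.
    """
    return 1.0 - 1.0 / partition_function(conc, array)


def _check_occ(values) -> np.ndarray:
    # p < 1 mathematically, but 1 - 1/Z rounds to exactly 1.0 at saturating
    # concentrations; tolerate the closure of the range
    p = np.asarray(values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1)):
        raise ValueError("occupancies must lie in [0, 1]")
    return p


def integrate_and(activator_occs: Sequence, repressor_occs: Sequence = ()) :
    """AND integration: product of activator occupancies and repressor complements.

    Empty input lists contribute a factor of one (the empty product), so with
    no inputs the synthesis potential is 1.
    """
    result = 1.0
    for p in activator_occs:
        result = result * _check_occ(p)
    for p in repressor_occs:
        result = result * (1.0 - _check_occ(p))
    return result


def integrate_or(occs: Iterable):
    """OR integration over independent activators: 1 - prod(1 - p_i)."""
    complement = 1.0
    for p in occs:
        complement = complement * (1.0 - _check_occ(p))
    return 1.0 - complement
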