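"""Closed-form population-genetic quantities for W<->S base composition.

The model is the classical reversible two-allele substitution framework
(Li/Bulmer): weak (W = A/T) and strong (S = G/C) alleles, mutation rates
u (S->W) and v (W->S) with bias kappa = u/v, and a population-scaled force
gamma = 4*Ne*s favoring S (directional selection on codon usage and/or
GC-biased gene conversion; the two are not distinguished here).

Under this model the per-site substitution (fixation) rates are

    r_{S->W} = u * gamma / (exp(gamma) - 1)
    r_{W->S} = v * gamma / (1 - exp(-gamma))

so their ratio is R = kappa * exp(-gamma), and the equilibrium GC content is
Q = 1 / (1 + kappa * exp(-gamma)).  If an ancestral population at equilibrium
for gamma experiences a proportional reduction of the force to p*gamma
(0 <= p < 1), the ratio of W->S to S->W substitution *counts* along the
descendant lineage is exp(-(1 - p) * gamma).

Also provided is the diversity-normalized frequency-skew statistic
delta_pi = k * a_{n-1} / S - 1, a close relative of Tajima's D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MutationScheme",
    "SelectionState",
    "DiversitySummary",
    "UndefinedStatisticError",
    "harmonic_number",
    "delta_pi",
    "fixation_rate_pair",
    "ratio_R",
    "gamma_from_R",
    "equilibrium_gc",
    "ratio_RN",
    "ratio_RN_long_form",
]

#: below this |gamma|, gamma/(exp(gamma)-1) is evaluated by series limit
_GAMMA_EPS = 1e-8


class UndefinedStatisticError(ValueError):
    """A summary statistic is undefined for the given input (e.g. S = 0)."""


@dataclass(frozen=True)
class MutationScheme:
    """Mutation rates between the strong (G/C) and weak (A/T) allele classes.

    Parameters
    ----------
    u : float
        S->W mutation rate per site per generation.
    v : float
        W->S mutation rate per site per generation.
    """

    u: float
    v: float

    def __post_init__(self) -> None:
        if not (self.u > 0 and self.v > 0):
            raise ValueError("mutation rates u and v must be positive")

    @property
    def kappa(self) -> float:
        """Mutational bias kappa = u/v (AT-biased mutation gives kappa > 1)."""
        return self.u / self.v


@dataclass(frozen=True)
class SelectionState:
    """State of the GC-favoring force on a lineage.

    gamma is the population-scaled intensity 4*Ne*s favoring S alleles, p is
    the proportional retention of an ancestral gamma along a descendant
    lineage (p = 1 means no change), and Q is the GC content at the ancestral
    node.
    """

    gamma: float
    p: float = 1.0
    Q: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("retention factor p must lie in [0, 1]")
        if not (0.0 <= self.Q <= 1.0):
            raise ValueError("GC content Q must lie in [0, 1]")


@dataclass(frozen=True)
class DiversitySummary:
    """Per-locus diversity summary: mean pairwise differences ``k``, number of
    segregating sites ``S`` and haploid sample size ``n``."""

    k: float
    S: int
    n: int

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.S < 0:
            raise ValueError("S must be non-negative")
        if self.n < 2:
            raise ValueError("need at least two sequences")


def harmonic_number(m: int) -> float:
    """Partial harmonic sum a_m = sum_{i=1}^{m} 1/i."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def delta_pi(d: DiversitySummary) -> float:
    """Diversity-normalized frequency-spectrum skew.

    Returns ``k * a_{n-1} / S - 1`` where ``a_{n-1} = sum_{i<n} 1/i``.  Under
    the neutral equilibrium expectation E[k] = S / a_{n-1} the statistic is 0;
    an excess of rare variants makes it negative, mirroring the sign of
    Tajima's D but with a denominator that scales with total diversity.

    Raises
    ------
    UndefinedStatisticError
        If there are no segregating sites.
    """
    if d.S == 0:
        raise UndefinedStatisticError("delta_pi undefined when S = 0")
    return d.k * harmonic_number(d.n - 1) / d.S - 1.0


def _gamma_over_expm1(x: float) -> float:
    """x / (exp(x) - 1), with the series limit 1 - x/2 + x^2/12 near 0."""
    if abs(x) < _GAMMA_EPS:
        return 1.0 - x / 2.0 + x * x / 12.0
    return x / math.expm1(x)


def fixation_rate_pair(m: MutationScheme, gamma: float) -> tuple[float, float]:
    """Per-site substitution rates (r_{S->W}, r_{W->S}) under force gamma.

    r_{S->W} = u * gamma/(e^gamma - 1) and r_{W->S} = v * gamma/(1 - e^-gamma);
    at gamma = 0 both reduce to the neutral rates (u, v).
    """
    r_sw = m.u * _gamma_over_expm1(gamma)
    r_ws = m.v * _gamma_over_expm1(-gamma)
    return r_sw, r_ws


def ratio_R(m: MutationScheme, gamma: float) -> float:
    """Substitution-rate ratio R = r_{S->W} / r_{W->S} = kappa * exp(-gamma)."""
    return m.kappa * math.exp(-gamma)


def gamma_from_R(R: float, kappa: float) -> float:
    """Invert R = kappa * exp(-gamma): gamma = ln(kappa / R).

    R is typically measured from substitution counts in a GC bin and kappa
    from a neutral reference class (e.g. short-intron sites).
    """
    if R <= 0 or kappa <= 0:
        raise ValueError("R and kappa must be positive")
    return math.log(kappa / R)


def equilibrium_gc(m: MutationScheme, gamma: float) -> float:
    """Equilibrium GC content Q = 1 / (1 + kappa * exp(-gamma))."""
    return 1.0 / (1.0 + m.kappa * math.exp(-gamma))


def ratio_RN(gamma: float, p: float) -> float:
    """Expected substitution-count ratio N_{W->S}/N_{S->W} after a reduction.

    For a lineage starting at equilibrium for gamma whose force is reduced to
    p*gamma, the count ratio is exp(-(1-p)*gamma): 1 at equilibrium (p = 1 or
    gamma = 0) and < 1 when a GC-favoring force has weakened.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    return math.exp(-(1.0 - p) * gamma)


def ratio_RN_long_form(m: MutationScheme, gamma: float, p: float) -> float:
    """Unsimplified count-ratio ((1-Q)(e^{p*gamma}-1)) / (kappa*Q*(1-e^{-p*gamma}))
    with Q at equilibrium for the ancestral gamma.

    Algebraically identical to :func:`ratio_RN`; retained as a cross-check and
    for use with a non-equilibrium ancestral Q.  The p*gamma -> 0 limit is
    taken by series.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    Q = equilibrium_gc(m, gamma)
    pg = p * gamma
    # (e^{pg}-1)/(1-e^{-pg}) = e^{pg}; keep the explicit ratio but guard pg ~ 0
    if abs(pg) < _GAMMA_EPS:
        core = 1.0 + pg
    else:
        core = math.expm1(pg) / -math.expm1(-pg)
    return (1.0 - Q) * core / (m.kappa * Q)
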