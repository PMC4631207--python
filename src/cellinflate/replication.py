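"""Cooper-Helmstetter multifork DNA replication model.

A replication round takes C minutes to copy the chromosome once and is
followed by a D-minute lag before the division it licenses.  When
C + D exceeds the doubling time tau, rounds overlap and cells carry
multiple nested fork generations ("multifork" replication).  The average
DNA per cell, in genome equivalents (units of one complete chromosome), is

    G = tau / (C ln 2) * (2^((C+D)/tau) - 2^(D/tau)),

which this module implements alongside an independent numerical oracle
that integrates per-cell DNA content over the extant-cell age
distribution 2 ln2/tau * 2^(-a/tau) -- the correctness criterion for the
closed form.  Also provided: inversion of the closed form for the
C-period given a DNA target, and the nucleotide-limited DNA-to-protein
ratio prediction for the overexpression branch (phi_nuc proportional to
lambda makes <D>/<P> proportional to phi_nuc/lambda, a constant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .allocation import AllocationParams, GrowthCondition, LimitationMode, phi_nuc

__all__ = [
    "ReplicationParams",
    "DnaState",
    "genome_equivalents_closed_form",
    "genome_equivalents_numeric",
    "dna_at_age",
    "fork_pair_generations",
    "c_period_from_dna",
    "dna_protein_ratio",
    "GENOME_MASS_FG",
]

#: Mass of one E. coli chromosome: 4.64 Mbp x 650 Da/bp ~ 5.01 fg.  A
#: calibration constant for converting assayed DNA mass to genome
#: equivalents.
GENOME_MASS_FG = 5.01


@dataclass(frozen=True)
class ReplicationParams:
    """C-period, D-period and doubling time, all in minutes."""

    c_period: float
    d_period: float
    tau: float

    def __post_init__(self) -> None:
        if self.c_period <= 0 or self.tau <= 0 or self.d_period < 0:
            raise ValueError("require c_period > 0, tau > 0, d_period >= 0")

    @classmethod
    def from_growth_rate(
        cls, lambda_per_h: float, c_period: float = 40.0, d_period: float = 20.0
    ) -> "ReplicationParams":
        """Params at a given growth rate (1/h) with textbook C and D."""
        return cls(c_period, d_period, 60.0 * np.log(2) / lambda_per_h)


@dataclass(frozen=True)
class DnaState:
    """DNA content and fork structure of one cell (or age class)."""

    genome_equivalents: float
    n_fork_pairs: int

    def __post_init__(self) -> None:
        if self.genome_equivalents < 1 or self.n_fork_pairs < 0:
            raise ValueError("genome_equivalents >= 1 and n_fork_pairs >= 0 required")


def genome_equivalents_closed_form(rep: ReplicationParams) -> float:
    """Population-average DNA per cell, in genome equivalents.

    Handles the multifork regime (C + D > tau, even C >> tau) with no
    special-casing; tends to 1 as tau -> infinity.
    """
    c, d, tau = rep.c_period, rep.d_period, rep.tau
    return tau / (c * np.log(2.0)) * (2.0 ** ((c + d) / tau) - 2.0 ** (d / tau))


def dna_at_age(age_min, rep: ReplicationParams):
    """DNA per cell, in genome equivalents, at cell age ``age_min``.

    The copy number of the chromosomal locus at map position x (origin at
    x=0, terminus at x=1) doubles C*(1-x) + D minutes before each
    division.  Integrating copy number along the chromosome -- done here
    exactly, segment by segment, after the substitution u = C(1-x) + D --
    gives the cell's DNA content.  Ages are taken modulo tau, except that
    age == tau is kept as the pre-division endpoint (DNA there is twice
    the newborn content).

    Accepts a scalar or array age; returns a float or ndarray.
    """
    c, d, tau = rep.c_period, rep.d_period, rep.tau
    a = np.atleast_1d(np.asarray(age_min, dtype=float))
    if np.any(a < 0):
        raise ValueError("ages must be non-negative")
    a = np.where(a > tau, a % tau, a)
    j_lo = int(np.floor(d / tau))
    j_hi = int(np.floor((c + d) / tau))
    total = np.zeros_like(a)
    for j in range(j_lo, j_hi + 1):
        lo = max(d, j * tau)
        hi = min(c + d, (j + 1) * tau)
        if hi <= lo:
            continue
        # locus doublings with u mod tau >= tau - a have already fired
        doubled = np.clip(hi - np.maximum(lo, (j + 1) * tau - a), 0.0, None)
        total += 2.0 ** j * ((hi - lo) + doubled)
    out = total / c
    return float(out[0]) if np.isscalar(age_min) else out


def fork_pair_generations(age_min: float, rep: ReplicationParams) -> DnaState:
    """DNA content plus the number of active fork generations at one age.

    A round initiated C + D before the division at lineage age (m+1) tau
    is active at age a when (m+1) tau - (C+D) <= a < (m+1) tau - D.
    """
    c, d, tau = rep.c_period, rep.d_period, rep.tau
    a = float(age_min) % tau if age_min > tau else float(age_min)
    n = 0
    m = 0
    while True:
        start = (m + 1) * tau - (c + d)
        if start > a:
            break
        if a < start + c:
            n += 1
        m += 1
    # rounds initiated in ancestors (start < 0) are still active if unfinished
    m = -1
    while True:
        start = (m + 1) * tau - (c + d)
        if start + c <= a:
            break
        if start <= a:
            n += 1
        m -= 1
        if start <= a - c - tau:  # safety; cannot trigger for valid params
            break
    return DnaState(genome_equivalents=float(dna_at_age(a, rep)), n_fork_pairs=n)


def genome_equivalents_numeric(rep: ReplicationParams, n_grid: int = 10**6) -> float:
    """Numerical age-distribution oracle for the closed form.

    Integrates :func:`dna_at_age` against the extant-cell age density
    2 ln2/tau * 2^(-a/tau) on [0, tau] by the trapezoid rule.  Agrees
    with :func:`genome_equivalents_closed_form` to well under 1e-6
    relative at the default grid.
    """
    if n_grid < 10**3:
        raise ValueError("n_grid must be at least 1000")
    tau = rep.tau
    a = np.linspace(0.0, tau, int(n_grid))
    density = (2.0 * np.log(2.0) / tau) * 2.0 ** (-a / tau)
    return float(np.trapezoid(density * dna_at_age(a, rep), a))


def c_period_from_dna(
    g_target: float, d_period: float, tau: float, tol: float = 1e-12
) -> float:
    """Invert the closed form: the C-period producing a DNA target.

    Average DNA is strictly increasing in C at fixed D and tau, so the
    root is found by bracketing (doubling the upper bound until the
    target is exceeded) and Brent's method.  Residual below 1e-9.

    Raises
    ------
    ValueError
        If ``g_target`` is below the single-chromosome limit reachable as
        C -> 0 (i.e. 2^(D/tau), which is >= 1).
    """
    if g_target < 1.0:
        raise ValueError("fewer than one genome equivalent per cell is unreachable")
    floor = 2.0 ** (d_period / tau)  # C -> 0 limit
    if g_target <= floor * (1.0 + 1e-12):
        raise ValueError(
            f"g_target={g_target} at or below the C->0 limit {floor:.6g} "
            "for these D and tau"
        )

    def f(c: float) -> float:
        return (
            genome_equivalents_closed_form(ReplicationParams(c, d_period, tau))
            - g_target
        )

    c_hi = tau
    while f(c_hi) < 0:
        c_hi *= 2.0
        if c_hi > 1e9:
            raise RuntimeError("failed to bracket the C-period")
    return float(brentq(f, 1e-9, c_hi, xtol=tol, rtol=8.9e-16, maxiter=200))


def dna_protein_ratio(
    cond: GrowthCondition,
    alloc_params: AllocationParams = AllocationParams(),
    k_nuc: float = 1.0,
) -> float:
    """Nucleotide-limited DNA-to-protein mass ratio prediction.

    In the nucleotide-limited regime the DNA synthesis rate lambda * <D>
    is proportional to the nucleotide-enzyme abundance phi_nuc * <P>, so
    <D>/<P> = k_nuc * phi_nuc(lambda) / lambda.  For the overexpression
    branch phi_nuc is itself proportional to lambda and the ratio is
    exactly constant in lambda.
    """
    if cond.mode is not LimitationMode.OE:
        raise ValueError("the nucleotide-limited ratio is modelled for mode='oe' only")
    if cond.lambda_ <= 0:
        raise ValueError("growth rate must be positive")
    return k_nuc * phi_nuc(cond, alloc_params) / cond.lambda_
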