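"""Proteome allocation laws under orthogonal growth limitations.

Exponentially growing *E. coli* can be slowed down in qualitatively
different ways: by poorer nutrients, by sub-lethal doses of a translation
inhibitor (chloramphenicol, "cm"), or by forced expression of a gratuitous
("useless") protein such as LacZ ("oe").  Each limitation reshapes the
proteome differently.  This module encodes the growth-rate dependence of
two proteome fractions that drive the rest of the package:

* ``phi_x`` -- the fraction of total protein belonging to the putative
  division-initiator sector X.  Under useless-protein overexpression most
  proteins, X included, are compressed in direct proportion to the growth
  rate lambda; under nutrient limitation X behaves like a constitutively
  expressed protein, phi_x proportional to (1 - lambda/lambda0); under
  chloramphenicol the measured cell size is flat, which phenomenologically
  corresponds to a constant phi_x.
* ``phi_nuc`` -- the fraction belonging to nucleotide-synthesis enzymes,
  which under overexpression also falls in proportion to lambda.  Only the
  overexpression branch is a modelled law (see ``PHI_NUC_MODELED_MODES``);
  the other modes return the reference value.

All branches are anchored at a common unperturbed reference condition
(glucose minimal medium, lambda_ref), so fold-changes between limitation
modes are parameter-free.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "LimitationMode",
    "GrowthCondition",
    "AllocationParams",
    "phi_x",
    "phi_nuc",
    "PHI_NUC_MODELED_MODES",
]


class LimitationMode(str, enum.Enum):
    """How steady-state growth is being limited."""

    NUTRIENT = "nutrient"  # poorer carbon source
    CM = "cm"              # sub-lethal chloramphenicol (translation inhibition)
    OE = "oe"              # useless-protein (LacZ) overexpression

    def __str__(self) -> str:  # keeps CSV/CLI output clean
        return self.value


def _as_mode(mode: "LimitationMode | str") -> LimitationMode:
    return mode if isinstance(mode, LimitationMode) else LimitationMode(mode)


@dataclass(frozen=True)
class GrowthCondition:
    """One steady-state culture: a limitation mode and its growth rate.

    Parameters
    ----------
    mode : LimitationMode or str
        Which growth limitation is applied.
    lambda_ : float
        Steady-state exponential growth rate, 1/h.  Must be positive; for
        the nutrient branch it must also lie below the allocation line's
        x-intercept ``lambda0`` (checked where the law is evaluated).
    label : str
        Free-text condition label, e.g. ``"mannose"``.
    """

    mode: LimitationMode
    lambda_: float
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", _as_mode(self.mode))
        if not self.lambda_ > 0:
            raise ValueError(f"growth rate must be positive, got {self.lambda_}")


@dataclass(frozen=True)
class AllocationParams:
    """Anchors and slopes of the allocation laws.

    ``phi_x_ref`` and ``phi_nuc_ref`` are arbitrary calibration constants:
    every observable quantity in the package is a ratio insensitive to
    them.  ``lambda_ref`` is the unperturbed glucose growth rate at which
    all three limitation branches coincide; ``lambda0`` is the x-intercept
    of the constitutive-protein line under nutrient limitation.
    """

    phi_x_ref: float = 0.01
    lambda_ref: float = 0.98   # 1/h, unperturbed glucose
    lambda0: float = 2.2       # 1/h, nutrient-line x-intercept
    phi_nuc_ref: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.phi_x_ref < 1:
            raise ValueError("phi_x_ref must lie in (0, 1)")
        if not 0 < self.phi_nuc_ref < 1:
            raise ValueError("phi_nuc_ref must lie in (0, 1)")
        if not 0 < self.lambda_ref < self.lambda0:
            raise ValueError("require 0 < lambda_ref < lambda0")

    @classmethod
    def from_config(cls, config: dict) -> "AllocationParams":
        """Build from a config mapping, honouring an ``allocation:`` block."""
        block = config.get("allocation", config)
        keys = ("phi_x_ref", "lambda_ref", "lambda0", "phi_nuc_ref")
        return cls(**{k: float(block[k]) for k in keys if k in block})


#: Modes for which the phi_nuc growth-rate law is actually modelled.  The
#: remaining modes return the reference fraction unchanged.
PHI_NUC_MODELED_MODES = frozenset({LimitationMode.OE})


def phi_x(cond: GrowthCondition, params: AllocationParams = AllocationParams()) -> float:
    """Division-protein proteome fraction phi_X(lambda) for one condition.

    The three branches::

        oe:        phi_x_ref * (lambda / lambda_ref)
        nutrient:  phi_x_ref * (1 - lambda/lambda0) / (1 - lambda_ref/lambda0)
        cm:        phi_x_ref

    All branches agree at lambda = lambda_ref.

    Raises
    ------
    ValueError
        For the nutrient branch with lambda >= lambda0 (the fraction would
        vanish or go negative).
    """
    lam = cond.lambda_
    if cond.mode is LimitationMode.OE:
        return params.phi_x_ref * lam / params.lambda_ref
    if cond.mode is LimitationMode.NUTRIENT:
        if lam >= params.lambda0:
            raise ValueError(
                f"nutrient-limited growth rate {lam}/h at or above the "
                f"allocation-line intercept lambda0={params.lambda0}/h"
            )
        return (
            params.phi_x_ref
            * (1.0 - lam / params.lambda0)
            / (1.0 - params.lambda_ref / params.lambda0)
        )
    # cm: size (hence 1/<P>, hence phi_x) is flat under sub-lethal doses
    return params.phi_x_ref


def phi_nuc(cond: GrowthCondition, params: AllocationParams = AllocationParams()) -> float:
    """Nucleotide-enzyme proteome fraction phi_nuc(lambda).

    Under useless-protein overexpression phi_nuc falls in direct
    proportion to the growth rate, ``phi_nuc_ref * lambda / lambda_ref``.
    For modes outside :data:`PHI_NUC_MODELED_MODES` no law is modelled and
    the reference fraction is returned unchanged.
    """
    if cond.lambda_ <= 0:
        raise ValueError("growth rate must be positive")
    if cond.mode in PHI_NUC_MODELED_MODES:
        return params.phi_nuc_ref * cond.lambda_ / params.lambda_ref
    return params.phi_nuc_ref
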