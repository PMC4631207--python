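"""Mean-field threshold-initiator model of cell division.

Division is triggered when the per-cell abundance of a dedicated division
protein X reaches a fixed absolute threshold P_X*.  At the population
level the fractional abundance phi_X = <P_X>/<P> then pins the average
protein content at division,

    <P*> = P_X* / phi_X,

so the extant-population mean protein is <P> = prefactor * <P*> with a
prefactor set by the age structure of the population: 3/4 for cells
uniformly distributed through the cycle, ln 2 for the extant snapshot of
an exponentially growing population of deterministic sizer cells (the
package default, validated against the agent-based simulator).

Because phi_X carries all the growth-rate dependence, 1/<P> versus lambda
traces the allocation law of each limitation mode, and size ratios between
modes at equal lambda are parameter-free fold predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .allocation import AllocationParams, GrowthCondition, LimitationMode, phi_x

__all__ = [
    "PREFACTOR_EXTANT",
    "PREFACTOR_UNIFORM_AGE",
    "MeanFieldState",
    "mean_protein",
    "size_ratio",
    "inverse_mean_protein_curve",
]

#: Extant-population mean size over division size for deterministic sizer
#: cells growing exponentially (snapshot age density 2 ln2/tau * 2^(-a/tau)).
PREFACTOR_EXTANT = math.log(2.0)

#: The same ratio if cell ages were uniformly distributed through the cycle.
PREFACTOR_UNIFORM_AGE = 0.75


@dataclass(frozen=True)
class MeanFieldState:
    """Mean-field prediction for one growth condition.

    ``mean_p_div`` is the average protein at division <P*> = P_X*/phi_X;
    ``mean_p`` = prefactor * mean_p_div is the extant-population average.
    Protein is in the same arbitrary units as ``p_x_star``.
    """

    cond: GrowthCondition
    phi_x: float
    p_x_star: float
    mean_p: float
    mean_p_div: float

    @property
    def inv_mean_p(self) -> float:
        return 1.0 / self.mean_p


def mean_protein(
    cond: GrowthCondition,
    alloc_params: AllocationParams = AllocationParams(),
    p_x_star: float = 1.0,
    prefactor: float = PREFACTOR_EXTANT,
) -> MeanFieldState:
    """Predict the average cellular protein content for one condition.

    Parameters
    ----------
    cond, alloc_params
        Growth condition and allocation anchors; phi_X(lambda) follows the
        condition's limitation-mode branch.
    p_x_star : float
        Absolute division threshold for protein X (arbitrary mass units);
        the same for every condition by model assumption.
    prefactor : float
        <P>/<P*> conversion, in (0.5, 1].  Defaults to ln 2.

    Returns
    -------
    MeanFieldState
        With ``mean_p_div = p_x_star / phi_x`` exact.
    """
    if not 0.5 < prefactor <= 1.0:
        raise ValueError("prefactor must lie in (0.5, 1]")
    fx = phi_x(cond, alloc_params)
    if fx <= 0:
        raise ValueError("phi_x must be positive")
    mean_p_div = p_x_star / fx
    return MeanFieldState(
        cond=cond,
        phi_x=fx,
        p_x_star=p_x_star,
        mean_p=prefactor * mean_p_div,
        mean_p_div=mean_p_div,
    )


def size_ratio(
    lambda_: float,
    mode_a: "LimitationMode | str",
    mode_b: "LimitationMode | str",
    alloc_params: AllocationParams = AllocationParams(),
) -> float:
    """Fold-change in mean cell protein, mode_a over mode_b, at equal lambda.

    Since <P> = prefactor * P_X* / phi_X and threshold and prefactor are
    condition-independent, the ratio reduces to phi_X(mode_b)/phi_X(mode_a)
    and is parameter-free apart from the allocation anchors.  At
    lambda = lambda_ref every mode pair gives 1.
    """
    fa = phi_x(GrowthCondition(mode_a, lambda_), alloc_params)
    fb = phi_x(GrowthCondition(mode_b, lambda_), alloc_params)
    return fb / fa


def inverse_mean_protein_curve(
    mode: "LimitationMode | str",
    lambdas: "Sequence[float] | Iterable[float]",
    alloc_params: AllocationParams = AllocationParams(),
    p_x_star: float = 1.0,
    prefactor: float = PREFACTOR_EXTANT,
) -> pd.DataFrame:
    """Tabulate 1/<P> against growth rate for one limitation mode.

    1/<P> is proportional to phi_X, so the overexpression branch is a line
    through the origin and the nutrient branch a line with x-intercept
    lambda0.  Returns a DataFrame with columns
    ``mode, lambda, phi_x, mean_p, inv_mean_p``.
    """
    rows = []
    for lam in np.asarray(list(lambdas), dtype=float):
        st = mean_protein(
            GrowthCondition(mode, float(lam)), alloc_params, p_x_star, prefactor
        )
        rows.append(
            {
                "mode": str(st.cond.mode),
                "lambda": float(lam),
                "phi_x": st.phi_x,
                "mean_p": st.mean_p,
                "inv_mean_p": st.inv_mean_p,
            }
        )
    return pd.DataFrame(rows)
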