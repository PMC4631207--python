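"""Statsmodels-style front end: fit the allocation laws to per-cell data.

:class:`ThresholdInitiatorModel` takes a table of per-cell protein
content versus growth rate across limitation modes (for example the
output of :func:`cellinflate.pipeline.per_cell`) and fits the mean-field
threshold-initiator predictions mode by mode:

* nutrient: 1/<P> = b0 + b1 * lambda, whose x-intercept estimates the
  allocation-line intercept lambda0;
* overexpression: 1/<P> = s * lambda through the origin (with the free
  intercept also fitted as a diagnostic of proportionality);
* chloramphenicol: 1/<P> constant (mean level).

The returned :class:`ThresholdInitiatorResults` carries the estimates,
their standard errors, R-squared diagnostics, a ``summary()`` table,
``predict``, parameter-free fold predictions via ``size_ratio``, a
simulator hook and a plot of the fitted 1/<P> lines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .allocation import AllocationParams, GrowthCondition, LimitationMode
from .pipeline import FitResult, fit_inverse_protein, per_cell, proportionality_fit
from .simulator import SimConfig, run_steady_state

__all__ = ["ThresholdInitiatorModel", "ThresholdInitiatorResults"]


class ThresholdInitiatorModel:
    """Mean-field threshold-initiator model bound to per-cell data.

    Parameters
    ----------
    data : DataFrame
        One row per measurement with columns ``mode`` (``nutrient`` /
        ``cm`` / ``oe``), ``lambda`` (growth rate, 1/h) and ``protein``
        or ``protein_fg`` (per-cell protein content, any fixed unit).

    Examples
    --------
    >>> from cellinflate import synthetic
    >>> samples = sum((synthetic.generate_bulk(s, seed=1)
    ...                for s in synthetic.default_condition_set()), [])
    >>> res = ThresholdInitiatorModel.from_bulk(samples).fit()
    >>> round(res.lambda0, 1)
    2.2
    """

    def __init__(self, data: pd.DataFrame):
        if "lambda" not in data.columns or "mode" not in data.columns:
            raise ValueError("data needs 'mode' and 'lambda' columns")
        pcol = "protein" if "protein" in data.columns else "protein_fg"
        if pcol not in data.columns:
            raise ValueError("data needs a 'protein' or 'protein_fg' column")
        self.data = data.copy()
        self.protein_column = pcol

    @classmethod
    def from_bulk(cls, samples, genome_mass_fg: float | None = None):
        """Build from bulk assay samples via the per-cell accounting."""
        kwargs = {} if genome_mass_fg is None else {"genome_mass_fg": genome_mass_fg}
        return cls(per_cell(samples, **kwargs))

    def fit(self) -> "ThresholdInitiatorResults":
        """Fit every limitation mode present in the data."""
        fits: dict = {}
        df = self.data
        pcol = self.protein_column
        if (df["mode"] == "nutrient").sum() >= 3:
            fits["nutrient"] = fit_inverse_protein(df, mode="nutrient")
        if (df["mode"] == "oe").sum() >= 3:
            sub = df[df["mode"] == "oe"]
            fits["oe"] = fit_inverse_protein(df, mode="oe")
            fits["oe_through_origin"] = proportionality_fit(
                sub["lambda"], 1.0 / sub[pcol]
            )
        if (df["mode"] == "cm").sum() >= 1:
            inv = 1.0 / df.loc[df["mode"] == "cm", pcol].to_numpy(float)
            fits["cm_level"] = (float(inv.mean()),
                                float(inv.std(ddof=1) / np.sqrt(inv.size))
                                if inv.size > 1 else float("nan"))
        if not fits:
            raise ValueError("no mode has enough data to fit")
        return ThresholdInitiatorResults(self, fits)


class ThresholdInitiatorResults:
    """Fit results for :class:`ThresholdInitiatorModel`."""

    def __init__(self, model: ThresholdInitiatorModel, fits: dict):
        self.model = model
        self.fits = fits

    # -- headline estimates -------------------------------------------------
    @property
    def lambda0(self) -> float:
        """Allocation-line x-intercept from the nutrient branch, 1/h."""
        fit: FitResult = self.fits["nutrient"]
        return fit.x_intercept

    @property
    def lambda0_se(self) -> float:
        return self.fits["nutrient"].x_intercept_se

    @property
    def params(self) -> pd.Series:
        out = {}
        for name in ("nutrient", "oe"):
            if name in self.fits:
                out[f"{name}_slope"] = self.fits[name].slope
                out[f"{name}_intercept"] = self.fits[name].intercept
        if "oe_through_origin" in self.fits:
            out["oe_origin_slope"] = self.fits["oe_through_origin"].slope
        if "nutrient" in self.fits:
            out["lambda0"] = self.lambda0
        if "cm_level" in self.fits:
            out["cm_inv_protein"] = self.fits["cm_level"][0]
        return pd.Series(out)

    def predict(self, mode, lambda_) -> np.ndarray:
        """Predicted per-cell protein at the given growth rate(s)."""
        lam = np.atleast_1d(np.asarray(lambda_, dtype=float))
        mode = str(LimitationMode(mode))
        if mode == "cm":
            inv = np.full_like(lam, self.fits["cm_level"][0])
        elif mode == "oe" and "oe_through_origin" in self.fits:
            inv = self.fits["oe_through_origin"].slope * lam
        else:
            f = self.fits[mode]
            inv = f.intercept + f.slope * lam
        return 1.0 / inv

    def allocation_params(self, lambda_ref: float = 0.98) -> AllocationParams:
        """Allocation anchors implied by the fit (lambda0 from the data)."""
        return AllocationParams(lambda_ref=lambda_ref, lambda0=self.lambda0)

    def size_ratio(self, lambda_: float, mode_a, mode_b) -> float:
        """Fold prediction between modes using the fitted lambda0."""
        from .meanfield import size_ratio as _sr

        return _sr(lambda_, mode_a, mode_b, self.allocation_params())

    # -- presentation --------------------------------------------------------
    def summary(self) -> SimpleTable:
        """Summary table of the per-mode fits."""
        rows, index = [], []
        for name in ("nutrient", "oe", "oe_through_origin"):
            if name not in self.fits:
                continue
            f = self.fits[name]
            rows.append(
                [
                    f"{f.slope:.5g}",
                    f"{f.slope_se:.2g}",
                    f"{f.intercept:.5g}",
                    f"{f.x_intercept:.4g}" if np.isfinite(f.x_intercept) else "--",
                    f"{f.r_squared:.4f}",
                    f"{f.n}",
                ]
            )
            index.append(name)
        if "cm_level" in self.fits:
            level, se = self.fits["cm_level"]
            rows.append([f"{0.0:.5g}", "--", f"{level:.5g}", "--", "--", "--"])
            index.append("cm (constant)")
        table = SimpleTable(
            rows,
            headers=["slope", "slope SE", "intercept", "x-intercept", "R^2", "n"],
            stubs=index,
            title="Threshold-initiator fits of 1/<P> vs growth rate",
        )
        return table

    def simulate(self, mode="nutrient", lambda_: float = 0.98, **kwargs):
        """Steady-state single-cell snapshot under the fitted allocation."""
        cfg = SimConfig(
            cond=GrowthCondition(mode, lambda_),
            alloc=self.allocation_params(),
            **kwargs,
        )
        return run_steady_state(cfg)

    def plot(self, ax=None):
        """Plot 1/<P> data and fitted lines per mode."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.model.data
        pcol = self.model.protein_column
        colors = {"nutrient": "tab:green", "cm": "tab:blue", "oe": "tab:red"}
        for mode, sub in df.groupby("mode"):
            ax.plot(
                sub["lambda"], 1.0 / sub[pcol], "o",
                color=colors.get(mode, "k"), label=mode,
            )
            lam = np.linspace(sub["lambda"].min(), sub["lambda"].max(), 50)
            try:
                ax.plot(lam, 1.0 / self.predict(mode, lam), "-",
                        color=colors.get(mode, "k"), alpha=0.7)
            except KeyError:
                pass
        ax.set_xlabel("growth rate $\\lambda$ (1/h)")
        ax.set_ylabel("1/$\\langle P\\rangle$ (1/protein units)")
        ax.legend()
        return ax
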