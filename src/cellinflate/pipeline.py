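"""Per-cell accounting from bulk measurements, and trend fits.

Culture-level totals (protein, RNA, DNA, dry mass per ml) divided by the
cell count per ml give per-cell quantities.  Which count to trust is
condition-dependent: plating for nutrient limitation at slow growth
rates (the Coulter counter undercounts cells near its detection limit),
the Coulter counter for translation inhibition and overexpression
(plating misses a non-viable fraction).  DNA mass converts to genome
equivalents through the chromosome mass constant (~5.01 fg).

Fits: ordinary least squares of 1/<P> on lambda per limitation mode
(the nutrient branch's x-intercept estimates the allocation-line
intercept lambda0, with a delta-method standard error), and
through-origin proportionality fits for tight linear correlations such
as dry mass versus volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .allocation import GrowthCondition, LimitationMode
from .replication import GENOME_MASS_FG
from .synthetic import BulkSample

__all__ = [
    "SLOW_GROWTH_THRESHOLD",
    "select_count",
    "per_cell",
    "FitResult",
    "fit_inverse_protein",
    "proportionality_fit",
    "reproduce",
]

#: Growth rate (1/h) below which nutrient-limited cultures are counted by
#: plating rather than by the Coulter counter.
SLOW_GROWTH_THRESHOLD = 0.7


def select_count(sample: BulkSample, cond: GrowthCondition | None = None):
    """Choose the trusted cell count for one sample.

    Returns ``(count_per_ml, method)`` with method ``"plating"`` for
    nutrient limitation below :data:`SLOW_GROWTH_THRESHOLD` and
    ``"coulter"`` otherwise.

    Raises
    ------
    ValueError
        If the mandated count is missing or non-positive.
    """
    mode = cond.mode if cond is not None else LimitationMode(sample.mode)
    lam = cond.lambda_ if cond is not None else sample.lambda_
    if mode is LimitationMode.NUTRIENT and lam < SLOW_GROWTH_THRESHOLD:
        method = "plating"
        count = sample.count_plating_ml
    else:
        method = "coulter"
        count = sample.count_coulter_ml
    if count is None or not count > 0:
        raise ValueError(f"missing or invalid {method} count for {sample.label}")
    return float(count), method


def per_cell(samples, genome_mass_fg: float = GENOME_MASS_FG) -> pd.DataFrame:
    """Per-cell quantities from bulk samples (one row per replicate).

    Each quantity is (total per ml) / (selected count per ml), expressed
    in femtograms; DNA is additionally converted to genome equivalents.
    Columns: ``condition, mode, lambda, replicate, count_method,
    protein_fg, rna_fg, dna_fg, dna_geq, drymass_fg,
    macromolecule_share``.
    """
    rows = []
    for s in samples:
        count, method = select_count(s)
        protein = s.protein_ug_ml / count * 1e9
        rna = s.rna_ug_ml / count * 1e9
        dna = s.dna_ug_ml / count * 1e9
        dry = s.drymass_ug_ml / count * 1e9
        rows.append(
            {
                "condition": s.label,
                "mode": s.mode,
                "lambda": s.lambda_,
                "replicate": s.replicate,
                "count_method": method,
                "protein_fg": protein,
                "rna_fg": rna,
                "dna_fg": dna,
                "dna_geq": dna / genome_mass_fg,
                "drymass_fg": dry,
                "macromolecule_share": (protein + rna + dna) / dry,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FitResult:
    """Slope/intercept fit summary.

    ``x_intercept`` is -intercept/slope (NaN for through-origin fits);
    ``x_intercept_se`` its delta-method standard error when available.
    """

    slope: float
    intercept: float
    x_intercept: float
    r_squared: float
    n: int
    slope_se: float = float("nan")
    intercept_se: float = float("nan")
    x_intercept_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("a fit needs at least 3 points")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")


def fit_inverse_protein(data, mode: str | None = None) -> FitResult:
    """OLS of inverse per-cell protein on growth rate for one mode.

    Parameters
    ----------
    data : DataFrame
        Needs columns ``lambda`` and one of ``protein`` /
        ``protein_fg``; filtered to ``mode`` when given (requires a
        ``mode`` column).

    Returns
    -------
    FitResult
        For the nutrient branch ``x_intercept`` estimates lambda0; for
        the overexpression branch the intercept is compatible with zero
        (direct proportionality through the origin).

    Raises
    ------
    ValueError
        With fewer than 3 conditions or degenerate growth rates.
    """
    df = data
    if mode is not None:
        df = df[df["mode"] == str(mode)]
    lam = np.asarray(df["lambda"], dtype=float)
    pcol = "protein" if "protein" in df.columns else "protein_fg"
    inv_p = 1.0 / np.asarray(df[pcol], dtype=float)
    if lam.size < 3:
        raise ValueError("need at least 3 conditions to fit")
    if np.ptp(lam) == 0:
        raise ValueError("degenerate growth rates")
    res = sm.OLS(inv_p, sm.add_constant(lam)).fit()
    b0, b1 = res.params
    se0, se1 = res.bse
    cov01 = np.asarray(res.cov_params())[0, 1]
    x_int = -b0 / b1
    # delta method: var(x) = (dx/db0)^2 v00 + (dx/db1)^2 v11 + 2 dx/db0 dx/db1 v01
    d0, d1 = -1.0 / b1, b0 / b1**2
    x_se = float(np.sqrt(max(d0 * d0 * se0**2 + d1 * d1 * se1**2 + 2 * d0 * d1 * cov01, 0.0)))
    return FitResult(
        slope=float(b1),
        intercept=float(b0),
        x_intercept=float(x_int),
        r_squared=float(min(max(res.rsquared, 0.0), 1.0)),
        n=int(lam.size),
        slope_se=float(se1),
        intercept_se=float(se0),
        x_intercept_se=x_se,
    )


def proportionality_fit(x, y) -> FitResult:
    """Through-origin least squares y = slope * x.

    ``r_squared`` is computed against the centred total sum of squares
    (clipped to [0, 1]) so that data unrelated to x scores near zero
    even when y has a non-zero mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired arrays with at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("proportionality fit expects positive data")
    slope = float(x @ y / (x @ x))
    resid = y - slope * x
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 0.0
    n = int(x.size)
    slope_se = float(np.sqrt((resid**2).sum() / (n - 1) / (x @ x)))
    return FitResult(
        slope=slope,
        intercept=0.0,
        x_intercept=float("nan"),
        r_squared=min(max(r2, 0.0), 1.0),
        n=n,
        slope_se=slope_se,
    )


def reproduce(config: dict | None = None, seed: int = 1, out_dir=None) -> dict:
    """Run the full synthetic chain and report the headline quantities.

    Generates the default condition panel, performs the per-cell
    accounting, fits the allocation trends, evaluates the mean-field and
    replication model predictions and a compact morphometry benchmark,
    and returns a machine-readable report.  All randomness derives from
    ``seed``.  When ``out_dir`` is given, the report (JSON), the bulk
    table and the per-cell table (CSV) are written there.
    """
    from . import meanfield, replication, synthetic
    from .allocation import AllocationParams
    from .morphometry import ImagingParams, render_population, segment_and_measure

    cal = synthetic.load_calibration(config.get("calibration") if config else None)
    alloc = AllocationParams.from_config(cal)
    noise_cv = cal.get("noise_cv", 0.05)
    rng_seeds = np.random.SeedSequence(seed).generate_state(8) % (2**31)

    specs = synthetic.default_condition_set(cal)
    samples = []
    for i, spec in enumerate(specs):
        samples.extend(
            synthetic.generate_bulk(
                spec, n_replicates=6, noise_cv=noise_cv,
                seed=int(rng_seeds[0]) + i, calibration=cal,
            )
        )
    percell = per_cell(samples, cal["genome_mass_fg"])
    by_cond = percell.groupby("condition").mean(numeric_only=True)

    size_fold = float(
        meanfield.size_ratio(0.2, LimitationMode.OE, LimitationMode.NUTRIENT, alloc)
    )
    oe_dna = float(by_cond.loc["lacZ-oe-slowest", "dna_geq"])
    nut_dna = float(by_cond.loc["slow-nutrient", "dna_geq"])

    series = synthetic.nutrient_series(
        np.linspace(0.3, 1.6, 10), noise_cv=noise_cv, seed=int(rng_seeds[1]), alloc=alloc
    )
    lam0_fit = fit_inverse_protein(series, mode="nutrient")

    rep = replication.ReplicationParams(40.0, 20.0, 100.0)
    geq_slow = replication.genome_equivalents_closed_form(rep)

    # compact morphometry benchmark
    spec_gl = specs[0]
    _, cells, volumes = synthetic.generate_population(
        spec_gl, n_cells=120, seed=int(rng_seeds[2]), calibration=cal
    )
    params = ImagingParams(shape=(900, 900))
    errs = []
    for i in range(0, 120, 15):
        batch = cells[i : i + 15]
        vols = volumes[i : i + 15]
        phase, _ = render_population(batch, params, seed=int(rng_seeds[3]) + i)
        measured, _, table = segment_and_measure(phase)
        if len(table) == len(batch):
            mv = np.sort(table["V_um3"].to_numpy())
            errs.extend(np.abs(mv - np.sort(vols)) / np.sort(vols))
    morpho_err = float(np.median(errs)) if errs else float("nan")

    report = {
        "size_fold_oe_vs_nutrient_at_0.2": size_fold,
        "hc_genome_equivalents_C40_D20_tau100": float(geq_slow),
        "oe_slowest_dna_geq": oe_dna,
        "dna_fold_oe_vs_nutrient": oe_dna / nut_dna,
        "lambda0_per_h": lam0_fit.x_intercept,
        "lambda0_se": lam0_fit.x_intercept_se,
        "macromolecule_share_pct": float(percell["macromolecule_share"].mean() * 100),
        "morphometry_median_volume_error": morpho_err,
        "n_conditions": len(specs),
        "seed": seed,
    }
    if out_dir is not None:
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        synthetic.bulk_table(samples).to_csv(out / "bulk_measurements.csv", index=False)
        percell.to_csv(out / "per_cell.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
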