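"""Synthetic culture-level and single-cell data generator.

Emulates the measurement campaign of a growth-limitation study: for each
steady-state condition a culture at OD600 ~ 0.4 is assayed for total
protein, RNA, DNA and dry mass per ml, and counted both with a Coulter
counter and by plating.  Per-cell targets come from the mean-field
threshold-initiator model (protein, in "glucose-cell units" with the
unperturbed glucose cell = 1) and calibrated DNA contents in genome
equivalents; assay noise is multiplicative lognormal.  Count densities
follow the opposite trend to cell size (bigger cells, fewer cells per ml
at fixed OD), and each counting method carries its documented bias:
plating slightly undercounts overexpression cultures (~10%) and
chloramphenicol cultures (~20%, dead-on-plate fraction), while the
Coulter counter undercounts small slow-growing nutrient-limited cells
near its detection limit.

Matching single-cell populations (size distributions whose shape
collapses under rescaling by the mean, and spherocylinder geometries for
the morphometry channel) are drawn either from the agent-based simulator
or from a lognormal surrogate of its steady-state size distribution.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allocation import AllocationParams, GrowthCondition, LimitationMode
from .meanfield import mean_protein
from .morphometry import Spherocylinder, length_from_volume
from .replication import (
    GENOME_MASS_FG,
    ReplicationParams,
    genome_equivalents_closed_form,
)
from .simulator import PopulationSnapshot, SimConfig, run_steady_state

__all__ = [
    "DEFAULT_CALIBRATION",
    "load_calibration",
    "ConditionSpec",
    "BulkSample",
    "default_condition_set",
    "generate_bulk",
    "generate_population",
    "nutrient_series",
    "bulk_table",
]

#: Default calibration.  Quantities that are measured biology are pinned
#: to the study conditions they emulate; everything without a printed
#: value (absolute masses, count densities) is an arbitrary but fixed
#: normalisation, chosen at realistic E. coli magnitudes.
DEFAULT_CALIBRATION: dict = {
    "allocation": {
        "phi_x_ref": 0.01,
        "lambda_ref": 0.98,   # 1/h, unperturbed glucose anchor
        "lambda0": 2.2,       # 1/h, nutrient allocation-line intercept
        "phi_nuc_ref": 0.02,
    },
    # macromolecular composition: protein+RNA+DNA account for ~90% of dry mass
    "macromolecule_share": 0.90,
    "genome_mass_fg": GENOME_MASS_FG,
    # absolute normalisations (arbitrary units, fixed once)
    "glucose_protein_fg": 155.0,       # protein per glucose cell
    "glucose_count_per_ml": 4.0e8,     # cells/ml at OD600 0.4 in glucose
    "od600": 0.4,
    # physical size conversion: constant dry-mass (protein) density
    "volume_per_glucose_unit_um3": 1.3,
    "cell_width_um": 0.9,
    "size_cv": 0.25,                   # width of single-cell size distributions
    # Cooper-Helmstetter defaults for nutrient-limited DNA
    "c_period_min": 40.0,
    "d_period_min": 20.0,
    # the slowest overexpression condition reaches ~8 genome equivalents;
    # slow nutrient-limited growth is calibrated at 2.0 (4-fold below)
    "oe_dna_slowest_geq": 8.0,
    "oe_slowest_lambda": 0.20,
    "slow_nutrient_dna_geq": 2.0,
    "cm_dna_geq": 1.9,
    # counting-method biases (multiplier applied to the true count)
    "count_bias": {
        "oe": {"coulter": 1.0, "plating": 0.9},
        "cm": {"coulter": 1.0, "plating": 0.8},
        "nutrient_slow": {"coulter": 0.85, "plating": 1.0},
        "nutrient_fast": {"coulter": 1.0, "plating": 1.0},
    },
    "slow_growth_threshold": 0.7,  # 1/h, below which Coulter undercounts
    # RNA/protein mass ratios per condition label (ribosome-content trends:
    # rises with nutrient quality, elevated under chloramphenicol)
    "rna_protein_ratio": {
        "glucose": 0.33,
        "mannose": 0.25,
        "slow-nutrient": 0.22,
        "cm": 0.45,
        "lacZ-oe": 0.35,
        "lacZ-oe-slowest": 0.35,
    },
    "noise_cv": 0.05,
    "conditions": [
        {"label": "glucose", "mode": "nutrient", "lambda": 0.98},
        {"label": "mannose", "mode": "nutrient", "lambda": 0.41},
        {"label": "slow-nutrient", "mode": "nutrient", "lambda": 0.20},
        {"label": "cm", "mode": "cm", "lambda": 0.32},
        {"label": "lacZ-oe", "mode": "oe", "lambda": 0.25},
        {"label": "lacZ-oe-slowest", "mode": "oe", "lambda": 0.20},
    ],
}


def load_calibration(path=None) -> dict:
    """Return the calibration dict, optionally overridden from a YAML file.

    The YAML file may override any subset of keys; nested mappings are
    merged shallowly per top-level key.
    """
    cal = copy.deepcopy(DEFAULT_CALIBRATION)
    if path is not None:
        import yaml

        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cal.get(key), dict):
                cal[key].update(val)
            else:
                cal[key] = val
    return cal


@dataclass(frozen=True)
class ConditionSpec:
    """Per-cell targets for one growth condition.

    ``protein_units`` is per-cell protein in glucose-cell units;
    ``dna_geq`` per-cell DNA in genome equivalents;
    ``rna_protein_ratio`` the RNA/protein mass ratio;
    ``macromolecule_share`` the (protein+RNA+DNA)/dry-mass fraction;
    ``count_bias`` maps method -> multiplier applied to the true count.
    """

    cond: GrowthCondition
    protein_units: float
    rna_protein_ratio: float
    dna_geq: float
    macromolecule_share: float
    count_bias: dict

    def __post_init__(self) -> None:
        if self.dna_geq < 1.0:
            raise ValueError("per-cell DNA below one genome equivalent")
        if not 0 < self.macromolecule_share <= 1:
            raise ValueError("macromolecule share must lie in (0, 1]")


def _dna_target(label: str, mode: LimitationMode, lam: float, cal: dict) -> float:
    """Calibrated per-cell DNA in genome equivalents for one condition."""
    c, d = cal["c_period_min"], cal["d_period_min"]
    if mode is LimitationMode.OE:
        # DNA tracks per-cell protein (attenuated constant ratio), pinned
        # at the slowest-OE calibration point
        return cal["oe_dna_slowest_geq"] * cal["oe_slowest_lambda"] / lam
    if mode is LimitationMode.CM:
        return cal["cm_dna_geq"]
    if lam < cal["slow_growth_threshold"] and label == "slow-nutrient":
        return cal["slow_nutrient_dna_geq"]
    rep = ReplicationParams.from_growth_rate(lam, c, d)
    return genome_equivalents_closed_form(rep)


def default_condition_set(calibration: dict | None = None) -> list:
    """The default panel of growth conditions with calibrated targets.

    Covers the unperturbed glucose reference, two slower nutrient
    limitations, a chloramphenicol condition and two useless-protein
    overexpression conditions down to the slowest (lambda = 0.2/h, ~8
    genome equivalents of DNA).  Per-cell protein targets come from the
    mean-field model relative to the glucose anchor.
    """
    cal = calibration or DEFAULT_CALIBRATION
    alloc = AllocationParams.from_config(cal)
    ref_state = mean_protein(
        GrowthCondition(LimitationMode.NUTRIENT, alloc.lambda_ref, "glucose"), alloc
    )
    specs = []
    for entry in cal["conditions"]:
        mode = LimitationMode(entry["mode"])
        lam = float(entry["lambda"])
        label = entry["label"]
        cond = GrowthCondition(mode, lam, label)
        protein = mean_protein(cond, alloc).mean_p / ref_state.mean_p
        if mode is LimitationMode.NUTRIENT:
            key = (
                "nutrient_slow"
                if lam < cal["slow_growth_threshold"]
                else "nutrient_fast"
            )
        else:
            key = mode.value
        specs.append(
            ConditionSpec(
                cond=cond,
                protein_units=protein,
                rna_protein_ratio=cal["rna_protein_ratio"].get(label, 0.3),
                dna_geq=_dna_target(label, mode, lam, cal),
                macromolecule_share=cal["macromolecule_share"],
                count_bias=dict(cal["count_bias"][key]),
            )
        )
    return specs


@dataclass(frozen=True)
class BulkSample:
    """One replicate of culture-level assays for one condition."""

    label: str
    mode: str
    lambda_: float
    od600: float
    protein_ug_ml: float
    rna_ug_ml: float
    dna_ug_ml: float
    drymass_ug_ml: float
    count_coulter_ml: float
    count_plating_ml: float
    replicate: int
    seed: int

    def __post_init__(self) -> None:
        for name in (
            "protein_ug_ml",
            "rna_ug_ml",
            "dna_ug_ml",
            "drymass_ug_ml",
            "count_coulter_ml",
            "count_plating_ml",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def generate_bulk(
    spec: ConditionSpec,
    n_replicates: int = 6,
    noise_cv: float = 0.05,
    seed: int = 0,
    calibration: dict | None = None,
) -> list:
    """Emulate the bulk assays for one condition.

    Totals per ml are (per-cell target) x (true count density) with
    independent mean-one lognormal noise per assay; the two count methods
    get their condition-specific biases.  The count density scales
    inversely with cell size so that OD 0.4 corresponds to fewer, larger
    cells.  Zero noise returns the targets exactly; a fixed seed gives
    identical tables.
    """
    if not 0 <= noise_cv <= 0.2:
        raise ValueError("noise_cv must lie in [0, 0.2]")
    cal = calibration or DEFAULT_CALIBRATION
    rng = np.random.default_rng(seed)
    protein_fg = spec.protein_units * cal["glucose_protein_fg"]
    rna_fg = protein_fg * spec.rna_protein_ratio
    dna_fg = spec.dna_geq * cal["genome_mass_fg"]
    dry_fg = (protein_fg + rna_fg + dna_fg) / spec.macromolecule_share
    count_true = cal["glucose_count_per_ml"] / spec.protein_units

    samples = []
    for rep in range(n_replicates):
        noise = _lognormal_factor(rng, noise_cv, 6)
        samples.append(
            BulkSample(
                label=spec.cond.label,
                mode=spec.cond.mode.value,
                lambda_=spec.cond.lambda_,
                od600=cal["od600"],
                protein_ug_ml=protein_fg * count_true * 1e-9 * noise[0],
                rna_ug_ml=rna_fg * count_true * 1e-9 * noise[1],
                dna_ug_ml=dna_fg * count_true * 1e-9 * noise[2],
                drymass_ug_ml=dry_fg * count_true * 1e-9 * noise[3],
                count_coulter_ml=count_true * spec.count_bias["coulter"] * noise[4],
                count_plating_ml=count_true * spec.count_bias["plating"] * noise[5],
                replicate=rep,
                seed=seed,
            )
        )
    return samples


def bulk_table(samples) -> pd.DataFrame:
    """Stack bulk samples into the canonical measurements table."""
    return pd.DataFrame(
        [
            {
                "condition": s.label,
                "mode": s.mode,
                "lambda": s.lambda_,
                "od600": s.od600,
                "protein_ug_ml": s.protein_ug_ml,
                "rna_ug_ml": s.rna_ug_ml,
                "dna_ug_ml": s.dna_ug_ml,
                "drymass_ug_ml": s.drymass_ug_ml,
                "count_coulter_ml": s.count_coulter_ml,
                "count_plating_ml": s.count_plating_ml,
                "replicate": s.replicate,
                "seed": s.seed,
            }
            for s in samples
        ]
    )


def generate_population(
    spec: ConditionSpec,
    n_cells: int = 1000,
    seed: int = 0,
    calibration: dict | None = None,
    use_simulator: bool = False,
):
    """Single-cell sizes and spherocylinder geometries for one condition.

    Sizes (protein, glucose-cell units) are drawn from the agent-based
    simulator when ``use_simulator`` is set, otherwise from a lognormal
    surrogate with the calibrated CV -- either way the distribution
    collapses across conditions once rescaled by its mean.  Volumes
    follow from the constant-density conversion, and each cell becomes a
    spherocylinder at the calibrated width with the length solving the
    volume formula (width is reduced with a warning for cells below the
    sphere limit).

    Returns ``(PopulationSnapshot, list[Spherocylinder], volumes_um3)``.
    """
    if n_cells < 100:
        raise ValueError("n_cells must be at least 100")
    cal = calibration or DEFAULT_CALIBRATION
    rng = np.random.default_rng(seed)
    if use_simulator:
        cfg = SimConfig(
            cond=spec.cond,
            alloc=AllocationParams.from_config(cal),
            n_cells_target=max(1000, n_cells),
            seed=seed,
        )
        snap = run_steady_state(cfg)
        sizes = snap.sizes[:n_cells] / snap.sizes.mean() * spec.protein_units
        ages = snap.ages[:n_cells]
    else:
        cv = cal["size_cv"]
        sigma = np.sqrt(np.log1p(cv * cv))
        sizes = spec.protein_units * rng.lognormal(-0.5 * sigma**2, sigma, n_cells)
        tau = np.log(2.0) / spec.cond.lambda_
        ages = tau * np.log2(1.0 + rng.random(n_cells))  # extant age distribution
        snap = PopulationSnapshot(
            sizes=sizes,
            ages=ages,
            label=spec.cond.label,
            timestamp=0.0,
            lambda_=spec.cond.lambda_,
            steady=True,
        )
    volumes = sizes * cal["volume_per_glucose_unit_um3"]
    width = cal["cell_width_um"]
    sphere_v = np.pi * width**3 / 6.0
    cells = []
    for v in volumes:
        w = width
        if v < sphere_v:
            import warnings

            w = (6.0 * v / np.pi) ** (1.0 / 3.0) * 0.999
            warnings.warn(
                "cell volume below the sphere limit; width reduced", stacklevel=2
            )
        cells.append(Spherocylinder(length_from_volume(v, w), w))
    return snap, cells, volumes


def nutrient_series(
    lambdas,
    noise_cv: float = 0.05,
    seed: int = 42,
    alloc: AllocationParams | None = None,
) -> pd.DataFrame:
    """Noisy mean-field protein measurements along a nutrient series.

    Used for growth-law recovery experiments: per-cell protein at each
    growth rate follows the mean-field nutrient branch (glucose-cell
    units) with mean-one multiplicative lognormal noise.  Returns a
    DataFrame with columns ``mode, lambda, protein``.
    """
    alloc = alloc or AllocationParams()
    rng = np.random.default_rng(seed)
    ref = mean_protein(
        GrowthCondition(LimitationMode.NUTRIENT, alloc.lambda_ref), alloc
    ).mean_p
    rows = []
    for lam in np.asarray(list(lambdas), dtype=float):
        p = mean_protein(
            GrowthCondition(LimitationMode.NUTRIENT, float(lam)), alloc
        ).mean_p
        rows.append(
            {
                "mode": "nutrient",
                "lambda": float(lam),
                "protein": p / ref * float(_lognormal_factor(rng, noise_cv)),
            }
        )
    return pd.DataFrame(rows)
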