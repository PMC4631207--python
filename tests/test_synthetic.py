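"""Synthetic-data generator: calibrated targets, noise model, invariants."""

import numpy as np
import pytest

from cellinflate.meanfield import size_ratio
from cellinflate.synthetic import (
    DEFAULT_CALIBRATION,
    bulk_table,
    default_condition_set,
    generate_bulk,
    generate_population,
    load_calibration,
    nutrient_series,
)


@pytest.fixture(scope="module")
def specs():
    return default_condition_set()


def _by_label(specs, label):
    return next(s for s in specs if s.cond.label == label)


def test_condition_panel_contents(specs):
    labels = {s.cond.label for s in specs}
    assert {"glucose", "mannose", "cm", "lacZ-oe", "lacZ-oe-slowest"} <= labels
    glucose = _by_label(specs, "glucose")
    assert glucose.cond.lambda_ == 0.98
    assert glucose.protein_units == pytest.approx(1.0, rel=1e-12)


def test_per_cell_protein_follows_mean_field_folds(specs):
    """The slowest OE cell carries ~8x the protein of a nutrient-limited
    cell at the same growth rate."""
    oe = _by_label(specs, "lacZ-oe-slowest")
    nut = _by_label(specs, "slow-nutrient")
    assert oe.cond.lambda_ == nut.cond.lambda_ == 0.2
    expected = size_ratio(0.2, "oe", "nutrient")
    assert oe.protein_units / nut.protein_units == pytest.approx(expected, rel=1e-12)
    assert oe.protein_units / nut.protein_units == pytest.approx(8.03, abs=0.01)


def test_dna_targets(specs):
    assert _by_label(specs, "lacZ-oe-slowest").dna_geq == pytest.approx(8.0)
    assert _by_label(specs, "slow-nutrient").dna_geq == pytest.approx(2.0)
    # faster nutrient conditions follow the replication model (< 2 geq)
    assert 1.0 <= _by_label(specs, "mannose").dna_geq < 2.0
    assert 1.0 <= _by_label(specs, "glucose").dna_geq < 2.0


def test_zero_noise_bulk_recovers_targets_exactly(specs):
    spec = _by_label(specs, "glucose")
    cal = DEFAULT_CALIBRATION
    samples = generate_bulk(spec, n_replicates=2, noise_cv=0.0, seed=0)
    for s in samples:
        count = s.count_coulter_ml
        assert s.protein_ug_ml / count * 1e9 == pytest.approx(
            spec.protein_units * cal["glucose_protein_fg"], rel=1e-12
        )
        assert s.dna_ug_ml / count * 1e9 == pytest.approx(
            spec.dna_geq * cal["genome_mass_fg"], rel=1e-12
        )
        macromolecules = s.protein_ug_ml + s.rna_ug_ml + s.dna_ug_ml
        assert macromolecules / s.drymass_ug_ml == pytest.approx(0.90, rel=1e-12)
        assert s.drymass_ug_ml >= macromolecules  # mass conservation


def test_bulk_seed_reproducibility(specs):
    spec = _by_label(specs, "mannose")
    t1 = bulk_table(generate_bulk(spec, seed=9))
    t2 = bulk_table(generate_bulk(spec, seed=9))
    assert t1.equals(t2)
    t3 = bulk_table(generate_bulk(spec, seed=10))
    assert not t1.equals(t3)


def test_count_method_biases(specs):
    """Plating undercounts oe (~10%) and cm (~20%); the Coulter counter
    undercounts small slow-growing nutrient-limited cells."""
    oe = generate_bulk(_by_label(specs, "lacZ-oe"), 1, noise_cv=0.0, seed=0)[0]
    assert oe.count_plating_ml / oe.count_coulter_ml == pytest.approx(0.9, rel=1e-12)
    cm = generate_bulk(_by_label(specs, "cm"), 1, noise_cv=0.0, seed=0)[0]
    assert cm.count_plating_ml / cm.count_coulter_ml == pytest.approx(0.8, rel=1e-12)
    slow = generate_bulk(_by_label(specs, "slow-nutrient"), 1, noise_cv=0.0, seed=0)[0]
    assert slow.count_coulter_ml < slow.count_plating_ml


def test_count_density_opposes_cell_size(specs):
    """Bigger cells, fewer cells per ml at matched optical density."""
    glucose = generate_bulk(_by_label(specs, "glucose"), 1, noise_cv=0.0, seed=0)[0]
    oe = generate_bulk(_by_label(specs, "lacZ-oe-slowest"), 1, noise_cv=0.0, seed=0)[0]
    ratio = glucose.count_coulter_ml / oe.count_coulter_ml
    assert ratio == pytest.approx(
        _by_label(specs, "lacZ-oe-slowest").protein_units, rel=1e-12
    )


def test_noise_cv_bounds(specs):
    with pytest.raises(ValueError):
        generate_bulk(_by_label(specs, "glucose"), noise_cv=0.5)


def test_generate_population_geometry(specs):
    spec = _by_label(specs, "glucose")
    snap, cells, volumes = generate_population(spec, n_cells=300, seed=1)
    assert len(cells) == 300
    cal = DEFAULT_CALIBRATION
    assert volumes.mean() == pytest.approx(
        spec.protein_units * cal["volume_per_glucose_unit_um3"], rel=0.05
    )
    # geometry inverts the volume formula at the calibrated width
    for cell, v in zip(cells[:10], volumes[:10]):
        assert cell.volume_um3 == pytest.approx(v, rel=1e-9)


def test_population_size_distributions_collapse(specs):
    """Mean-normalised size distributions coincide across conditions."""
    from scipy.stats import ks_2samp

    a = generate_population(_by_label(specs, "glucose"), 5000, seed=2)[0]
    b = generate_population(_by_label(specs, "lacZ-oe-slowest"), 5000, seed=3)[0]
    stat = ks_2samp(a.sizes / a.sizes.mean(), b.sizes / b.sizes.mean()).statistic
    assert stat < 0.05


def test_nutrient_series_noise_free_is_exact_line():
    df = nutrient_series(np.linspace(0.3, 1.6, 10), noise_cv=0.0, seed=0)
    inv = 1.0 / df["protein"].to_numpy()
    lam = df["lambda"].to_numpy()
    slope = np.polyfit(lam, inv, 1)
    assert -slope[1] / slope[0] == pytest.approx(2.2, rel=1e-9)


def test_load_calibration_yaml_override(tmp_path):
    path = tmp_path / "calibration.yaml"
    path.write_text("oe_dna_slowest_geq: 6.0\ncount_bias:\n  cm: {plating: 0.7}\n")
    cal = load_calibration(path)
    assert cal["oe_dna_slowest_geq"] == 6.0
    assert cal["count_bias"]["cm"]["plating"] == 0.7
    assert cal["count_bias"]["oe"]["plating"] == 0.9  # untouched defaults
    assert DEFAULT_CALIBRATION["oe_dna_slowest_geq"] == 8.0
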