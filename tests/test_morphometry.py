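"""Morphometry: volume formula, rendering ground truth, segmentation
accuracy, DAPI integrated density."""

import math
import warnings

import numpy as np
import pytest

from cellinflate.morphometry import (
    ImagingParams,
    Spherocylinder,
    integrate_dapi,
    length_from_volume,
    render_population,
    save_tiff,
    load_tiff,
    segment_and_measure,
    spherocylinder_volume,
)

CLEAN = ImagingParams(noise_sd=0.0, blur_sigma_px=1.0, shape=(256, 256))


@pytest.mark.parametrize(
    "l, w, expected",
    [
        (2.0, 2.0, 4.0 / 3.0 * math.pi),        # sphere limit, R = 1
        (3.0, 1.0, math.pi * 0.25 * (3 - 1 / 3.0)),
        (2.0, 1.0, math.pi * 0.25 * (2 - 1 / 3.0)),
    ],
)
def test_spherocylinder_volume(l, w, expected):
    assert spherocylinder_volume(l, w) == pytest.approx(expected, rel=1e-12)


def test_volume_derived_values():
    assert spherocylinder_volume(3.0, 1.0) == pytest.approx(2.0944, abs=1e-4)
    assert spherocylinder_volume(2.0, 1.0) == pytest.approx(1.3090, abs=1e-4)


def test_volume_feret_contract_and_monotonicity():
    with pytest.raises(ValueError):
        spherocylinder_volume(1.0, 2.0)
    assert spherocylinder_volume(3.0, 1.0) < spherocylinder_volume(3.5, 1.0)
    assert spherocylinder_volume(3.0, 1.0) < spherocylinder_volume(3.0, 1.2)


def test_length_from_volume_round_trip():
    v = spherocylinder_volume(2.0, 1.0)
    assert length_from_volume(v, 1.0) == pytest.approx(2.0, rel=1e-12)
    with pytest.raises(ValueError):
        length_from_volume(0.01, 1.0)  # below the sphere limit


def test_rendered_mask_area_matches_analytic():
    """Zero noise, no blur: segmented area within 2% of the analytic
    spherocylinder cross-section pi R^2 + 2R(L - 2R)."""
    params = ImagingParams(noise_sd=0.0, blur_sigma_px=0.0, shape=(256, 256))
    phase, _ = render_population([Spherocylinder(3.0, 1.0)], params, seed=1)
    _, labels, _ = segment_and_measure(phase)
    area = (labels > 0).sum() * params.pixel_size_um**2
    r, length = 0.5, 3.0
    analytic = math.pi * r * r + 2 * r * (length - 2 * r)
    assert area == pytest.approx(analytic, rel=0.02)


def test_render_determinism():
    phase1, dapi1 = render_population([Spherocylinder(3.0, 1.0)], CLEAN, seed=5)
    phase2, dapi2 = render_population([Spherocylinder(3.0, 1.0)], CLEAN, seed=5)
    assert np.array_equal(phase1.pixels, phase2.pixels)
    assert np.array_equal(dapi1.pixels, dapi2.pixels)


def test_placement_failure_raises():
    cells = [Spherocylinder(10.0, 1.0)] * 10  # cannot fit in a 256 px frame
    with pytest.raises(RuntimeError):
        render_population(cells, CLEAN, seed=0, max_tries=20)


def test_segmentation_recovers_length_and_width():
    """Rendered 3 x 1 um cell at 0.05 um/px: L and W recovered within
    2 px at arbitrary orientation."""
    tol = 2 * CLEAN.pixel_size_um
    for seed in range(5):  # different random orientations
        phase, _ = render_population([Spherocylinder(3.0, 1.0)], CLEAN, seed=seed)
        _, _, table = segment_and_measure(phase)
        assert len(table) == 1
        assert table.L_um[0] == pytest.approx(3.0, abs=tol)
        assert table.W_um[0] == pytest.approx(1.0, abs=tol)


def test_segmentation_empty_image():
    img = np.random.default_rng(0).normal(0.75, 0.02, (128, 128))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cells, labels, table = segment_and_measure(img, pixel_size_um=0.05)
    assert cells == [] or all(c.length_um < 0.5 for c in cells)


def test_population_volume_benchmark():
    """Median relative volume error < 5% across 500 rendered cells."""
    rng = np.random.default_rng(7)
    params = ImagingParams(shape=(900, 900))
    errors = []
    for i in range(20):
        lengths = rng.uniform(1.8, 4.5, 25)
        batch = [Spherocylinder(float(l), 0.9) for l in lengths]
        phase, _ = render_population(batch, params, seed=100 + i)
        _, _, table = segment_and_measure(phase)
        assert len(table) == 25
        measured = np.sort(table["V_um3"].to_numpy())
        truth = np.sort([b.volume_um3 for b in batch])
        errors.extend(np.abs(measured - truth) / truth)
    assert len(errors) == 500
    assert np.median(errors) < 0.05
    # end-to-end population mean within 5%
    assert np.mean(measured) == pytest.approx(np.mean(truth), rel=0.05)


def test_dapi_integrated_density_tracks_dna():
    """A cell rendered with twice the reference DNA integrates to twice
    the density (within 2%), and calibration converts to genome
    equivalents."""
    cells = [Spherocylinder(3.0, 1.0), Spherocylinder(3.0, 1.0)]
    phase, dapi = render_population(cells, CLEAN, seed=3, dna=[1.0, 2.0])
    _, labels, _ = segment_and_measure(phase)
    table = integrate_dapi(dapi, labels)
    dens = np.sort(table["integrated_density"].to_numpy())
    assert dens[1] / dens[0] == pytest.approx(2.0, rel=0.02)
    calibrated = integrate_dapi(
        dapi, labels, reference_density=dens[0], reference_genome_equivalents=1.0
    )
    assert np.sort(calibrated["genome_equivalents"].to_numpy())[1] == pytest.approx(
        2.0, rel=0.02
    )


def test_dapi_zero_channel_gives_zero():
    phase, _ = render_population([Spherocylinder(3.0, 1.0)], CLEAN, seed=2)
    _, labels, _ = segment_and_measure(phase)
    table = integrate_dapi(np.zeros(phase.pixels.shape), labels)
    assert np.allclose(table["integrated_density"], 0.0)


def test_dapi_population_summary_sample():
    """Per-condition DAPI summaries are reported as mean and SD over a
    ~20-cell sample."""
    rng = np.random.default_rng(4)
    cells = [Spherocylinder(3.0, 1.0) for _ in range(20)]
    dna = rng.uniform(1.0, 4.0, 20)
    params = ImagingParams(noise_sd=0.0, shape=(1200, 1200))
    phase, dapi = render_population(cells, params, seed=4, dna=dna)
    _, labels, _ = segment_and_measure(phase)
    table = integrate_dapi(dapi, labels)
    assert len(table) == 20
    scale = table["integrated_density"].sum() / dna.sum()
    assert table["integrated_density"].mean() / scale == pytest.approx(
        dna.mean(), rel=0.03
    )


def test_dapi_shape_mismatch_raises():
    phase, dapi = render_population([Spherocylinder(3.0, 1.0)], CLEAN, seed=2)
    with pytest.raises(ValueError):
        integrate_dapi(dapi, np.zeros((10, 10), dtype=int))


def test_tiff_round_trip(tmp_path):
    phase, _ = render_population([Spherocylinder(3.0, 1.0)], CLEAN, seed=6)
    path = tmp_path / "phase.tiff"
    save_tiff(path, phase)
    back = load_tiff(path, CLEAN.pixel_size_um)
    _, _, table = segment_and_measure(back)
    assert len(table) == 1
    assert table.L_um[0] == pytest.approx(3.0, abs=0.1)
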