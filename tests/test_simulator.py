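"""Agent-based simulator: sizer fixed point, extant statistics, adder
behaviour, distribution collapse, DNA attachment, determinism."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from cellinflate.allocation import AllocationParams, GrowthCondition
from cellinflate.replication import (
    ReplicationParams,
    genome_equivalents_closed_form,
)
from cellinflate.simulator import (
    SimConfig,
    attach_dna,
    init_population,
    run_steady_state,
    sample_extant,
    step_population,
)

ALLOC = AllocationParams()


def _cfg(mode="nutrient", lam=0.98, **kw):
    defaults = dict(
        cond=GrowthCondition(mode, lam),
        alloc=ALLOC,
        n_cells_target=2000,
        div_noise_cv=0.0,
        partition_noise_cv=0.0,
        seed=11,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def test_zero_noise_division_at_fixed_point():
    """After burn-in every division happens at the deterministic sizer
    fixed point (the adder's 2x birth size under full consumption)."""
    cfg = _cfg()
    snap = run_steady_state(cfg, record_divisions=True)
    log = snap.division_log
    assert log.shape[0] > 100
    assert np.allclose(log[:, 1], cfg.division_size, rtol=1e-9)


def test_zero_noise_interdivision_time_is_doubling_time():
    """A newborn at the fixed point divides after exactly ln2/lambda."""
    cfg = _cfg()
    lam = cfg.cond.lambda_
    # start below the renormalisation cap so no cell is ever subsampled away
    pop = init_population(cfg, n0=1000)
    # place a marker cell exactly at birth on the fixed trajectory
    pop.p[0] = cfg.division_size / 2.0
    pop.px[0] = 0.0
    pop.age[0] = 0.0
    dt = 0.005 / lam
    # evolve just short of one doubling time: no division yet for the marker
    tau = np.log(2) / lam
    p_expected = cfg.division_size / 2 * np.exp(lam * (dt * int(tau / dt * 0.9)))
    for _ in range(int(tau / dt * 0.9)):
        step_population(pop, dt, cfg)
    # the marker lineage is identifiable by its exact size trajectory
    assert np.min(np.abs(pop.p - p_expected)) < 1e-9 * p_expected


def test_zero_noise_sizes_bounded_by_division_size():
    cfg = _cfg(mode="oe", lam=0.5)
    snap = run_steady_state(cfg)
    div = cfg.division_size
    assert snap.sizes.min() >= div / 2 * (1 - 1e-9)
    assert snap.sizes.max() <= div * (1 + 1e-9)


def test_extant_mean_over_division_size_near_ln2():
    cfg = _cfg(n_cells_target=4000)
    snap = run_steady_state(cfg)
    assert snap.sizes.mean() / cfg.division_size == pytest.approx(np.log(2), rel=0.02)


def test_mean_field_consistency_no_consumption_variant():
    """Without consumption the division size is p_x_star/phi_x, matching
    the mean-field <P*> exactly; the snapshot mean is ln2 times that."""
    cfg = _cfg(consume_x=False, n_cells_target=4000)
    from cellinflate.allocation import phi_x

    assert cfg.division_size == pytest.approx(1.0 / phi_x(cfg.cond, ALLOC), rel=1e-12)
    snap = run_steady_state(cfg)
    assert snap.sizes.mean() / cfg.division_size == pytest.approx(np.log(2), rel=0.02)


def test_adder_added_size_independent_of_birth_size():
    """Full consumption makes added protein = p_x_star/phi_x regardless of
    birth size: regression slope of (added vs birth) is ~0."""
    cfg = _cfg(partition_noise_cv=0.05, div_noise_cv=0.0, n_cells_target=3000, seed=7)
    snap = run_steady_state(cfg, record_divisions=True)
    birth, division = snap.division_log[:, 0], snap.division_log[:, 1]
    added = division - birth
    slope = np.polyfit(birth, added, 1)[0]
    assert abs(slope) < 0.1
    expected_added = cfg.p_x_star / cfg.phi_x
    assert added.mean() == pytest.approx(expected_added, rel=0.02)


def test_size_distribution_collapse_across_conditions():
    """Mean-normalised size distributions from different limitation modes
    are statistically indistinguishable (KS < 0.05 at n = 10^4)."""
    snaps = []
    for mode, lam, seed in [("oe", 0.25, 1), ("nutrient", 0.98, 2)]:
        cfg = _cfg(
            mode=mode, lam=lam, seed=seed,
            div_noise_cv=0.1, partition_noise_cv=0.05, n_cells_target=10_000,
        )
        snaps.append(run_steady_state(cfg))
    a, b = (s.sizes / s.sizes.mean() for s in snaps)
    assert ks_2samp(a, b).statistic < 0.05


def test_snapshot_determinism():
    cfg = _cfg(div_noise_cv=0.1, partition_noise_cv=0.05, seed=123)
    s1 = run_steady_state(cfg)
    s2 = run_steady_state(cfg)
    assert np.array_equal(s1.sizes, s2.sizes)
    assert np.array_equal(s1.ages, s2.ages)


def test_dt_accuracy_contract_enforced():
    cfg = _cfg()
    pop = init_population(cfg, n0=2000)
    with pytest.raises(ValueError):
        step_population(pop, 0.02 / cfg.cond.lambda_, cfg)


def test_early_snapshot_flagged_not_steady():
    cfg = _cfg()
    pop = init_population(cfg, n0=2000)
    step_population(pop, 0.005 / cfg.cond.lambda_, cfg)
    assert not sample_extant(pop, cfg).steady


def test_attach_dna_slow_growth_limit():
    cfg = _cfg()
    snap = run_steady_state(cfg)
    rep = ReplicationParams(1e-6, 0.0, 1e9)
    dna = attach_dna(snap, rep)
    assert np.allclose(dna, 1.0, atol=1e-6)


@pytest.mark.parametrize(
    "lam, c, d",
    [(0.41, 40.0, 20.0), (0.25, 760.0, 20.0)],
)
def test_attach_dna_mean_matches_closed_form(lam, c, d):
    """Snapshot-average DNA agrees with the Cooper-Helmstetter average
    when the replication clock matches the growth rate."""
    cfg = _cfg(lam=lam, n_cells_target=10_000, seed=5)
    snap = run_steady_state(cfg)
    rep = ReplicationParams.from_growth_rate(lam, c, d)
    dna = attach_dna(snap, rep)
    closed = genome_equivalents_closed_form(rep)
    # tolerance covers Monte-Carlo error plus the slow clonal phase drift
    # of a finite renormalised population
    assert dna.mean() == pytest.approx(closed, rel=0.02)


def test_config_validation():
    with pytest.raises(ValueError):
        _cfg(div_noise_cv=0.5)
    with pytest.raises(ValueError):
        _cfg(n_cells_target=10)
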