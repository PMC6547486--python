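import numpy as np
import pytest
from scipy.stats import special_ortho_group

import oracle
from conftest import three_pair_toy_chain
from andis.geometry import build_local_frame
from andis.interaction import enumerate_pairs
from andis.potential import (ANGLE_SHAPE, RW_SHAPE, AnglePotential,
                             Potential, RWPotential)
from andis.scoring import (CUTOFF_GRID, ScoringConfig, cutoff_sweep,
                           score_structure)


def test_mode_is_a_pure_function_of_cutoff():
    assert ScoringConfig(7.0).mode == "weighted-angle"
    assert ScoringConfig(9.0).mode == "weighted-angle"
    assert ScoringConfig(9.5).mode == "angle"
    assert not ScoringConfig(9.5).uses_weights      # w == 1 at 9.5
    assert ScoringConfig(10.0).mode == "combined"
    assert ScoringConfig(15.0).mode == "combined"
    assert len(CUTOFF_GRID) == 17


def test_off_grid_cutoff_rejected():
    with pytest.raises(ValueError):
        ScoringConfig(9.25)
    with pytest.raises(ValueError):
        ScoringConfig(6.5)


def test_three_pair_toy_total_matches_hand_sum(table):
    chain = three_pair_toy_chain()
    pairs = list(enumerate_pairs(chain, r_max=7.0, with_weights=True))
    assert len(pairs) == 3
    assert all(p.weight == 1.0 for p in pairs)

    E = np.zeros(ANGLE_SHAPE)
    expected_total = 0.0
    fill = 0.7
    for p in pairs:
        # bins recomputed with the independent hand arithmetic
        g = p.geometry
        d = oracle.distance_bin_by_hand(g.r)
        assert d == g.dist_bin
        bins = [oracle.angle_bin_by_hand(g.theta_a, 15.0),
                oracle.angle_bin_by_hand(g.theta_b, 15.0),
                oracle.angle_bin_by_hand(g.phi_a, 30.0),
                oracle.angle_bin_by_hand(g.phi_b, 30.0),
                oracle.angle_bin_by_hand(g.chi, 30.0)]
        assert tuple(bins) == g.angle_bins
        for k in range(5):
            E[k, p.type_a, p.type_b, d, bins[k]] = fill
            expected_total += fill
            fill += 0.3
    pot = Potential(angle=AnglePotential(E=E),
                    rw=RWPotential(E=np.zeros(RW_SHAPE)))
    res = score_structure(chain, pot, ScoringConfig(r_cut=7.0))
    assert res.n_pairs == 3
    assert res.energy == pytest.approx(expected_total, rel=1e-12)


def test_zero_potential_scores_zero(hairpin_chain):
    pot = Potential(angle=AnglePotential(E=np.zeros(ANGLE_SHAPE)),
                    rw=RWPotential(E=np.zeros(RW_SHAPE)))
    res = score_structure(hairpin_chain, pot, ScoringConfig(r_cut=7.0))
    assert res.energy == 0.0 and res.n_pairs > 0


def test_combined_mode_applies_half_angle_plus_rw(hairpin_chain,
                                                  small_potential):
    """At r_cut >= 10 the per-pair score is 0.5*E_AG + E_RW, via an
    independent per-pair lookup loop."""
    config = ScoringConfig(r_cut=12.0)
    res = score_structure(hairpin_chain, small_potential, config)
    total = 0.0
    for p in enumerate_pairs(hairpin_chain, r_max=12.0):
        eag = sum(small_potential.angle.E[k, p.type_a, p.type_b,
                                          p.geometry.dist_bin,
                                          p.geometry.angle_bins[k]]
                  for k in range(5))
        erw = small_potential.rw.E[p.type_a, p.type_b, p.geometry.dist_bin]
        total += 0.5 * eag + erw
    assert res.energy == pytest.approx(total, rel=1e-9)


def test_unweighted_angle_mode_at_9_5(hairpin_chain, small_potential):
    res = score_structure(hairpin_chain, small_potential,
                          ScoringConfig(r_cut=9.5))
    total = 0.0
    for p in enumerate_pairs(hairpin_chain, r_max=9.5):
        total += sum(small_potential.angle.E[k, p.type_a, p.type_b,
                                             p.geometry.dist_bin,
                                             p.geometry.angle_bins[k]]
                     for k in range(5))
    assert res.energy == pytest.approx(total, rel=1e-9)


def test_energy_rigid_body_invariant(hairpin_chain, small_potential):
    rng = np.random.default_rng(0)
    R = special_ortho_group.rvs(3, random_state=rng)
    t = rng.normal(size=3) * 50.0
    moved = hairpin_chain.with_coords(hairpin_chain.coords_array() @ R.T + t)
    for r_cut in (7.0, 9.5, 15.0):
        e0 = score_structure(hairpin_chain, small_potential,
                             ScoringConfig(r_cut=r_cut)).energy
        e1 = score_structure(moved, small_potential,
                             ScoringConfig(r_cut=r_cut)).energy
        assert e1 == pytest.approx(e0, rel=1e-9)


def test_sweep_equals_independent_scoring(hairpin_chain, small_potential):
    grid = [7.0, 8.5, 9.5, 10.0, 14.5, 15.0]
    table = cutoff_sweep({"x": hairpin_chain}, small_potential, grid=grid)
    assert list(table.r_cut) == grid
    for _, row in table.iterrows():
        direct = score_structure(hairpin_chain, small_potential,
                                 ScoringConfig(r_cut=row.r_cut))
        assert row.energy == direct.energy
        assert row.n_pairs == direct.n_pairs
    # pair count is non-decreasing in the cutoff
    assert table.n_pairs.is_monotonic_increasing


def test_additivity_within_a_mode(hairpin_chain, small_potential):
    """E(15.0) - E(14.5) is exactly the shell contribution 14.5 <= r < 15."""
    res15 = score_structure(hairpin_chain, small_potential,
                            ScoringConfig(r_cut=15.0))
    res145 = score_structure(hairpin_chain, small_potential,
                             ScoringConfig(r_cut=14.5))
    shell = 0.0
    for p in enumerate_pairs(hairpin_chain, r_max=15.0):
        if 14.5 <= p.geometry.r < 15.0:
            eag = sum(small_potential.angle.E[k, p.type_a, p.type_b,
                                              p.geometry.dist_bin,
                                              p.geometry.angle_bins[k]]
                      for k in range(5))
            shell += 0.5 * eag + small_potential.rw.E[
                p.type_a, p.type_b, p.geometry.dist_bin]
    assert res15.energy - res145.energy == pytest.approx(shell, rel=1e-9,
                                                         abs=1e-9)


def test_missing_rw_matrix_raises_for_combined_mode(hairpin_chain):
    pot = Potential(angle=AnglePotential(E=np.zeros(ANGLE_SHAPE)), rw=None)
    with pytest.raises(ValueError, match="random-walk"):
        score_structure(hairpin_chain, pot, ScoringConfig(r_cut=15.0))


def test_per_pair_normalization(hairpin_chain, small_potential):
    raw = score_structure(hairpin_chain, small_potential,
                          ScoringConfig(r_cut=15.0))
    norm = score_structure(hairpin_chain, small_potential,
                           ScoringConfig(r_cut=15.0, per_pair=True))
    assert norm.energy == pytest.approx(raw.energy / raw.n_pairs)
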