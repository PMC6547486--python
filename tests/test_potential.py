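import numpy as np
import pytest

from andis import build_chain
from andis.geometry import N_ANGLE_BINS
from andis.interaction import chain_pair_table
from andis.potential import (ANGLE_SHAPE, OCC_SHAPE, RW_SHAPE, MatrixError,
                             AngleCountTensor, AnglePotential, Potential,
                             RWPotential, RWStatistics, accumulate,
                             accumulate_pair_table, derive_angle_potential,
                             derive_rw_potential, load_potential,
                             read_header, rw_reference_bin_probabilities,
                             save_potential)
from andis.synthetic import make_training_corpus


@pytest.fixture(scope="module")
def accumulated():
    """Counts from a 6-chain corpus, weighted mode."""
    tensors = AngleCountTensor.empty()
    rw = RWStatistics()
    for chain in make_training_corpus(6, seed=2):
        accumulate(chain, tensors, rw, mode="weighted")
    return tensors, rw


def test_empty_tensor_initialization():
    t = AngleCountTensor.empty()
    assert t.counts.shape == ANGLE_SHAPE
    assert t.raw_occurrence.shape == OCC_SHAPE
    assert (t.counts == 0.1).all()
    assert (t.raw_occurrence == 0).all()


def test_invalid_chain_rejected():
    tensors = AngleCountTensor.empty()
    with pytest.raises(ValueError, match="length < 30"):
        accumulate(build_chain("A" * 10), tensors)


def test_single_pair_updates_ten_angle_cells(hairpin_chain):
    """One observed pair adds its weight to 5 cells per direction and +1
    occurrence per direction, at the pair's distance bin."""
    full = chain_pair_table(hairpin_chain, r_max=15.0)
    k = int(np.argmin(np.abs(full.r - 5.0)))  # some mid-range pair

    class OneRow:
        m = full.m[k:k + 1]; n = full.n[k:k + 1]
        type_a = full.type_a[k:k + 1]; type_b = full.type_b[k:k + 1]
        sep = full.sep[k:k + 1]; r = full.r[k:k + 1]
        dist_bin = full.dist_bin[k:k + 1]; bins = full.bins[:, k:k + 1]
        weight = np.array([0.25])

        def __len__(self):
            return 1

    tensors = AngleCountTensor.empty()
    accumulate_pair_table(OneRow(), tensors, None, chain_length=50,
                          weighted=True)
    added = tensors.counts - 0.1
    assert added.sum() == pytest.approx(10 * 0.25)
    assert (added > 0).sum() <= 10  # mirror cells may coincide if a == b
    assert tensors.raw_occurrence.sum() == 10
    a, b, d = int(full.type_a[k]), int(full.type_b[k]), int(full.dist_bin[k])
    assert added[0, a, b, d, full.bins[0, k]] == pytest.approx(0.25)
    # mirrored direction: theta role swaps onto the (b, a) slice
    assert added[1, b, a, d, full.bins[0, k]] == pytest.approx(0.25)


def test_distance_5A_lands_in_bin_8(hairpin_chain):
    from andis.geometry import distance_bin
    assert distance_bin(5.0) == 8


def test_mirror_symmetry_of_counts(accumulated):
    tensors, _ = accumulated
    c = tensors.counts
    # equal up to summation order of the two accumulation directions
    np.testing.assert_allclose(c[0], np.swapaxes(c[1], 0, 1), rtol=1e-12)
    np.testing.assert_allclose(c[2], np.swapaxes(c[3], 0, 1), rtol=1e-12)
    np.testing.assert_allclose(c[4], np.swapaxes(c[4], 0, 1), rtol=1e-12)
    occ = tensors.raw_occurrence
    np.testing.assert_array_equal(occ[0], np.swapaxes(occ[1], 0, 1))


def test_uniform_counts_give_zero_energy():
    tensors = AngleCountTensor.empty()
    tensors.counts[0, 1, 2, 5, :] = 7.5
    tensors.raw_occurrence[0, 1, 2, 5] = 88
    E = derive_angle_potential(tensors).E
    np.testing.assert_allclose(E[0, 1, 2, 5], 0.0, atol=1e-12)


def test_occurrence_below_threshold_zeroes_slice():
    tensors = AngleCountTensor.empty()
    tensors.counts[0, 1, 2, 5, 3] = 100.0
    tensors.raw_occurrence[0, 1, 2, 5] = 19
    E = derive_angle_potential(tensors).E
    assert (E[0, 1, 2, 5] == 0).all()
    tensors.raw_occurrence[0, 1, 2, 5] = 20
    E = derive_angle_potential(tensors).E
    assert (E[0, 1, 2, 5] != 0).any()


def test_hot_bin_energy_arithmetic():
    """All mass in one bin (counts 100.1 hot, 0.1 in the 11 others, slice
    total 101.2): E(hot) = -ln(12*100.1/101.2) ~ -2.474 and E(cold) =
    -ln(12*0.1/101.2) ~ +4.435 — verified by independent arithmetic."""
    tensors = AngleCountTensor.empty()
    tensors.counts[2, 4, 9, 7, 5] = 100.1
    tensors.raw_occurrence[2, 4, 9, 7] = 100
    E = derive_angle_potential(tensors).E
    assert E[2, 4, 9, 7, 5] == pytest.approx(-np.log(12 * 100.1 / 101.2),
                                             rel=1e-12)
    assert E[2, 4, 9, 7, 0] == pytest.approx(-np.log(12 * 0.1 / 101.2),
                                             rel=1e-12)
    assert E[2, 4, 9, 7, 5] == pytest.approx(-2.474, abs=5e-4)
    assert E[2, 4, 9, 7, 0] == pytest.approx(4.435, abs=5e-4)


def test_probability_normalization_of_populated_slices(accumulated):
    tensors, _ = accumulated
    mask = tensors.raw_occurrence >= 20
    assert mask.any()
    c = tensors.counts[mask]
    p = c / c.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
    E = derive_angle_potential(tensors).E
    boltz = np.exp(-E[mask]).sum(axis=1) / N_ANGLE_BINS
    np.testing.assert_allclose(boltz, 1.0, atol=1e-9)


def test_planted_bias_recovered_as_energy_minimum(table):
    from andis.synthetic import PlantedBias
    bias = PlantedBias(type_a=("ALA", "CB"), type_b=("SER", "OG"),
                       dist_bin=8, angle_kind=0, hot_bin=3)
    chains = make_training_corpus(8, seed=0, planted_bias=bias,
                                  length_range=(40, 60))
    tensors = AngleCountTensor.empty()
    for c in chains:
        accumulate(c, tensors, None, mode="unweighted")
    ia, ib = table.index("ALA", "CB"), table.index("SER", "OG")
    assert tensors.raw_occurrence[0, ia, ib, 8] >= 20
    E = derive_angle_potential(tensors).E
    assert int(E[0, ia, ib, 8].argmin()) == 3


def test_rw_reference_probabilities_are_a_distribution():
    q = rw_reference_bin_probabilities(80, 3.8)
    assert q.shape == (29,)
    assert (q > 0).all()
    assert q.sum() == pytest.approx(1.0, abs=1e-12)
    # the un-normalized chain-ratio factor equals 1 at r = r_cut
    from andis.potential import _rw_chain_factor
    f = _rw_chain_factor(np.array([15.0]), 80, 3.8)
    assert f[0] / f[0] == 1.0


def test_rw_self_consistency_on_reference_sampled_corpus():
    rng = np.random.default_rng(9)
    L, n_pairs = 120, 300_000
    q = rw_reference_bin_probabilities(L, 3.8)
    stats = RWStatistics()
    counts = rng.multinomial(n_pairs, q).astype(float)
    stats.n_obs[0, 1, :] = counts
    stats.n_obs[1, 0, :] = counts
    per = np.zeros((167, 167))
    per[0, 1] = per[1, 0] = n_pairs
    stats.per_protein.append(per)
    stats.lengths.append(L)
    E = derive_rw_potential(stats).E[0, 1]
    sel = q * n_pairs >= 1e3
    assert np.abs(E[sel]).max() < 0.1


def test_rw_single_bin_sign_structure():
    """One pair type observed in a single bin: negative there, capped
    positive in every other populated bin."""
    stats = RWStatistics()
    stats.n_obs[3, 5, 10] = 500.0
    stats.n_obs[5, 3, 10] = 500.0
    per = np.zeros((167, 167))
    per[3, 5] = per[5, 3] = 500.0
    stats.per_protein.append(per)
    stats.lengths.append(60)
    pot = derive_rw_potential(stats)
    E = pot.E[3, 5]
    assert E[10] < 0
    others = np.delete(np.arange(29), 10)
    assert (E[others] == 10.0).all()
    # untouched type pairs have zero observed and zero expected -> 0
    assert (pot.E[0, 0] == 0).all()


def test_rw_r_cut_mismatch_raises():
    stats = RWStatistics(r_cut_ref=15.0)
    stats.per_protein.append(np.zeros((167, 167)))
    stats.lengths.append(50)
    with pytest.raises(ValueError, match="r_cut_ref"):
        derive_rw_potential(stats, r_cut_ref=10.0)


def _toy_potential():
    rng = np.random.default_rng(1)
    angle = AnglePotential(E=rng.normal(size=(5, 4, 4, 29, 12)))
    rw = RWPotential(E=rng.normal(size=(4, 4, 29)), kuhn_length=3.8)
    return Potential(angle=angle, rw=rw,
                     header={"mode": "weighted", "n_proteins": 3})


def test_save_load_round_trip_is_bitwise(tmp_path):
    pot = _toy_potential()
    path = tmp_path / "matrix.npz"
    save_potential(pot, path)
    back = load_potential(path)
    np.testing.assert_array_equal(back.angle.E, pot.angle.E)
    np.testing.assert_array_equal(back.rw.E, pot.rw.E)
    assert back.header["mode"] == "weighted"


def test_header_readable_without_tensors(tmp_path):
    pot = _toy_potential()
    path = tmp_path / "matrix.npz"
    save_potential(pot, path)
    header = read_header(path)
    assert header["mode"] == "weighted"
    assert header["version"] == "andis-matrix/1"
    assert "checksum_angle" in header


def test_truncated_file_fails_checksum_or_read(tmp_path):
    pot = _toy_potential()
    path = tmp_path / "matrix.npz"
    save_potential(pot, path)
    data = path.read_bytes()
    path.write_bytes(data[:len(data) // 2])
    with pytest.raises(MatrixError):
        load_potential(path)


def test_corrupted_tensor_fails_checksum(tmp_path):
    pot = _toy_potential()
    path = tmp_path / "matrix.npz"
    save_potential(pot, path)
    pot.angle.E[0, 0, 0, 0, 0] += 1.0  # mutate after checksumming
    save2 = tmp_path / "matrix2.npz"
    save_potential(pot, save2)
    # splice header of file 1 onto tensors of file 2 by hand
    import json
    import numpy as np
    with np.load(path) as a, np.load(save2) as b:
        arrays = {"E_angle": b["E_angle"], "E_rw": b["E_rw"],
                  "header": a["header"]}
    np.savez(path, **arrays)
    with pytest.raises(MatrixError, match="checksum"):
        load_potential(path)


def test_rw_totals_consistency(accumulated):
    """Summing N_obs over bins equals the per-protein totals summed over
    proteins (the reference cutoff covers the whole distance range)."""
    _, rw = accumulated
    lhs = rw.n_obs.sum(axis=2)
    rhs = np.sum(rw.per_protein, axis=0)
    np.testing.assert_array_equal(lhs, rhs)
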