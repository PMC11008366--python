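"""Binding matrix, contrast statistics, bands and pyramidalization."""

import math

import numpy as np
import pytest

from hbscreen.endgroups import parse_code
from hbscreen.energies import EnergyRecord, SurrogateParams
from hbscreen.errors import MissingPairError, UndefinedCorrelationError
from hbscreen.fixtures import surrogate_matrix, toy_geometry
from hbscreen.selectivity import (
    TETRAHEDRAL_ANGLE,
    BindingMatrix,
    band_report,
    build_matrix,
    contrast_binary,
    contrast_generalized,
    correlate_contrast_dihedral,
    pyramidalization,
    select_candidates,
)

from conftest import random_matrix, CODES_12


def _rec(x, y, pose, be):
    """Record whose raw binding energy equals ``be``."""
    return EnergyRecord(x, y, pose, E_complex=-be,
                        E_X_isolated=0.0, E_Y_isolated=0.0)


# ---------------------------------------------------------------------------
# matrix building

def test_build_matrix_takes_per_cell_maximum():
    records = [_rec("X-h", "Y-h", "p1", 3.0), _rec("X-h", "Y-h", "p2", 7.0),
               _rec("X-h", "X-h", "p1", 1.0), _rec("Y-h", "Y-h", "p1", 0.0)]
    M = build_matrix(records)
    assert M.energy("X-h", "X-h") == 1.0
    assert M.energy("X-h", "Y-h") == 7.0
    assert M.provenance_for("X-h", "Y-h")["pose_id"] == "p2"
    np.testing.assert_allclose(M.E, [[1.0, 7.0], [7.0, 0.0]])


def test_reversed_records_fill_the_same_cell():
    records = [_rec("Y-h", "X-h", "p1", 5.0),
               _rec("X-h", "X-h", "p", 0.0), _rec("Y-h", "Y-h", "p", 0.0)]
    M = build_matrix(records, roster=["X-h", "Y-h"])
    assert M.energy("X-h", "Y-h") == 5.0
    assert M.energy("Y-h", "X-h") == 5.0


def test_missing_pairs_are_listed():
    records = [_rec("X-h", "Y-h", "p", 5.0), _rec("X-h", "X-h", "p", 0.0)]
    with pytest.raises(MissingPairError) as err:
        build_matrix(records, roster=["X-h", "Y-h"])
    assert ("Y-h", "Y-h") in err.value.pairs


def test_matrix_invariant_under_roster_permutation():
    codes = CODES_12[:6]
    M1 = random_matrix(codes, seed=5)
    perm = codes[::-1]
    M2 = BindingMatrix(perm, M1.E[::-1, ::-1])
    for x in codes:
        for y in codes:
            assert M1.energy(x, y) == pytest.approx(M2.energy(x, y))


def test_unordered_cell_count():
    M = random_matrix(CODES_12, seed=0)
    assert M.n_unordered_pairs == 12 * 13 // 2


def test_square_and_long_csv_round_trip(tmp_path):
    M = random_matrix(CODES_12[:5], seed=9)
    sq = tmp_path / "m.csv"
    M.to_square_csv(sq)
    back = BindingMatrix.from_square_csv(sq)
    assert back.roster == M.roster
    np.testing.assert_allclose(back.E, M.E, atol=1e-6)
    lg = tmp_path / "long.csv"
    M.to_long_csv(lg)
    back2 = BindingMatrix.from_long_csv(lg)
    np.testing.assert_allclose(back2.E, M.E, atol=1e-6)


# ---------------------------------------------------------------------------
# contrasts

def test_binary_contrast_examples():
    M = BindingMatrix(["X-h", "Y-h"], [[0.0, 20.0], [20.0, 0.0]])
    assert contrast_binary(M, "X-h", "Y-h") == 20.0
    M = BindingMatrix(["X-h", "Y-h"], [[10.0, 15.0], [15.0, 4.0]])
    assert contrast_binary(M, "X-h", "Y-h") == pytest.approx(8.0)
    assert contrast_binary(M, "X-h", "X-h") == 0.0
    with pytest.raises(KeyError):
        contrast_binary(M, "X-h", "Z-h")


def test_generalized_contrast_examples():
    E = [[2.0, 20.0, 12.0], [20.0, 3.0, 1.0], [12.0, 1.0, 0.0]]
    M = BindingMatrix(["X-h", "Y-h", "Z-h"], E)
    # two-letter context reduces to E_XY - max homo energy
    assert contrast_generalized(M, "X-h", "Y-h", {"X-h", "Y-h"}) == \
        pytest.approx(20.0 - 3.0)
    assert contrast_generalized(M, "X-h", "Y-h", {"X-h", "Y-h", "Z-h"}) == \
        pytest.approx(20.0 - 12.0)
    with pytest.raises(ValueError):
        contrast_generalized(M, "X-h", "Y-h", {"X-h"})


def test_contrast_identities_on_random_matrices():
    for seed in range(20):
        M = random_matrix(CODES_12, seed=seed)
        x, y = M.roster[seed % 12], M.roster[(seed + 5) % 12]
        if x == y:
            continue
        small = contrast_generalized(M, x, y, {x, y})
        # mean of homo energies <= max of them
        assert contrast_binary(M, x, y) >= small - 1e-12
        # monotone nonincreasing in context
        prev = small
        context = {x, y}
        for z in M.roster:
            context.add(z)
            value = contrast_generalized(M, x, y, context)
            assert value <= prev + 1e-12
            prev = value


def test_select_candidates_matches_brute_filter():
    M = random_matrix(CODES_12, seed=3)
    got = select_candidates(M, threshold=5.0)
    want = sorted(
        ((x, y) for i, x in enumerate(M.roster) for y in M.roster[i + 1:]
         if contrast_binary(M, x, y) > 5.0),
        key=lambda p: -M.energy(*p),
    )
    assert [(s.x, s.y) for s in got] == [tuple(p) for p in want]
    assert all(s.E_C_binary > 5.0 for s in got)
    # energies sorted descending
    assert all(a.E_XY >= b.E_XY for a, b in zip(got, got[1:]))


def test_candidate_summaries_flag_canonical_and_mixed():
    M = BindingMatrix(["HH-h", "NN-h", "HNH-hh"],
                      [[0.0, 12.0, 2.0], [12.0, 0.0, 9.0], [2.0, 9.0, 1.0]])
    summaries = {(s.x, s.y): s for s in select_candidates(M, threshold=0.0)}
    s = summaries[("HH-h", "NN-h")]
    assert s.canonical and not s.mixed and s.class_pair == "DD:AA"
    s = summaries[("NN-h", "HNH-hh")]
    assert not s.canonical and s.mixed


def test_threshold_above_everything_selects_nothing():
    M = random_matrix(CODES_12, seed=1)
    assert select_candidates(M, threshold=1e6) == []


# ---------------------------------------------------------------------------
# band report

def test_band_report_gap_and_best():
    M = BindingMatrix(
        ["A-h", "B-h", "C-h", "D-h"],
        np.array([
            [0.0, 7.0, 9.0, 12.0],
            [7.0, 0.0, 2.0, 2.0],
            [9.0, 2.0, 0.0, 2.0],
            [12.0, 2.0, 2.0, 0.0],
        ]),
    )
    cands = [s for s in select_candidates(M, threshold=4.0)]
    rep = band_report(M, cands, band_edges=[6.0, 10.0, 14.0])
    energies = sorted(s.E_XY for s in cands)
    assert energies == [7.0, 9.0, 12.0]
    assert rep.max_gap == pytest.approx(3.0)
    (lo1, hi1, best1), (lo2, hi2, best2) = rep.bands
    assert {best1.E_XY, best2.E_XY} <= {7.0, 9.0, 12.0}
    assert best2.E_XY == 12.0


def test_band_report_single_candidate():
    M = BindingMatrix(["A-h", "B-h"], [[0.0, 8.0], [8.0, 0.0]])
    cands = select_candidates(M, threshold=4.0)
    rep = band_report(M, cands, band_edges=[6.0, 10.0])
    assert rep.max_gap == 0.0
    assert rep.bands[0][2].E_XY == 8.0


# ---------------------------------------------------------------------------
# pyramidalization

def test_planar_amine_angle_zero():
    geom = toy_geometry(parse_code("HH-h", planarity=1.0))
    assert pyramidalization(geom, geom.amino_nitrogens) == pytest.approx(0.0)


def test_tetrahedral_vectors_give_54_74():
    # bond vectors along cube diagonals, explicit vector-arithmetic oracle
    coords = np.array([
        [0.0, 0.0, 0.0],              # N
        [1.0, 1.0, 1.0],              # C (ring)
        [1.0, -1.0, -1.0],            # H
        [-1.0, 1.0, -1.0],            # H
    ]) / math.sqrt(3.0)
    angle = pyramidalization((["N", "C", "H", "H"], coords), [0],
                             bond_cutoff=1.5)
    assert angle == pytest.approx(math.degrees(math.atan(math.sqrt(2.0))),
                                  abs=1e-6)
    assert angle == pytest.approx(54.7356, abs=1e-3)


def test_mean_over_two_nitrogens():
    g_planar = toy_geometry(parse_code("H-h", planarity=1.0))
    g_pyr = toy_geometry(parse_code("H-h", planarity=0.0))
    coords = np.vstack([g_planar.coords, g_pyr.coords + [30.0, 0.0, 0.0]])
    symbols = g_planar.symbols + g_pyr.symbols
    ids = [g_planar.amino_nitrogens[0],
           g_planar.n_atoms + g_pyr.amino_nitrogens[0]]
    angle = pyramidalization((symbols, coords), ids)
    assert angle == pytest.approx(TETRAHEDRAL_ANGLE / 2.0, abs=1e-6)


def test_wrong_neighbor_count_raises():
    geom = toy_geometry(parse_code("N-h"))  # pyridinic N has one C neighbour
    with pytest.raises(ValueError, match="neighbou?rs"):
        pyramidalization(geom, [1])


# ---------------------------------------------------------------------------
# contrast / dihedral correlation

def test_perfect_anticorrelation():
    contrasts = [10.0, 8.0, 6.0, 4.0]
    angles = [0.0, 10.0, 20.0, 30.0]
    rep = correlate_contrast_dihedral(contrasts, angles)
    assert rep.n == 4
    assert rep.r == pytest.approx(-1.0)


def test_zero_variance_is_an_error():
    with pytest.raises(UndefinedCorrelationError):
        correlate_contrast_dihedral([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
    with pytest.raises(ValueError):
        correlate_contrast_dihedral([1.0, 2.0], [0.0, 1.0])


def test_surrogate_planarity_sweep_anticorrelates():
    """Lower amino planarity -> larger dihedral angle -> stronger donor homo
    pairing -> smaller contrast: Pearson r must be negative."""
    contrasts, angles = [], []
    for planarity in (0.0, 0.25, 0.5, 0.75, 1.0):
        donor = parse_code("HH-hh", planarity=planarity)
        acceptor = parse_code("NN-h", planarity=1.0)
        M = surrogate_matrix([donor, acceptor], SurrogateParams())
        contrasts.append(contrast_binary(M, donor.code, acceptor.code))
        angles.append((1.0 - planarity) * TETRAHEDRAL_ANGLE)
    rep = correlate_contrast_dihedral(contrasts, angles)
    assert rep.r < 0.0
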