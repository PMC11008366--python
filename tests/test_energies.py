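"""Binding-energy formulas, surrogate scorer and energy-table I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbscreen.endgroups import EndGroup, SitePattern, parse_code
from hbscreen.energies import (
    HARTREE_TO_KCAL,
    EnergyRecord,
    SurrogateParams,
    be_relax,
    be_rigid,
    binding_energy,
    read_energy_table,
    select_best_pose,
    surrogate_pair_energy,
    write_energy_table,
)
from hbscreen.errors import EnergyTableError, NoPlanarPoseError, \
    UndefinedQuantityError
from hbscreen.poses import Alignment, PairPose, enumerate_alignments, mirror


def _group(letters, skeleton="h", planarity=1.0):
    return EndGroup(SitePattern.from_letters(letters), skeleton,
                    planarity=planarity)


# ---------------------------------------------------------------------------
# binding-energy formulas

@pytest.mark.parametrize(
    "ex, ey, ec, expected",
    [(-10, -12, -30, 8.0), (0, 0, 0, 0.0), (-5, -5, -10, 0.0)],
)
def test_binding_energy_formula(ex, ey, ec, expected):
    assert binding_energy(ex, ey, ec) == pytest.approx(expected)


def test_be_relax_and_rigid():
    rec = EnergyRecord("X-h", "Y-h", "f0s0", E_complex=-310.0,
                       E_X_isolated=-100.0, E_Y_isolated=-200.0,
                       E_complex_CP=-315.0, E_X_in_complex=-99.0,
                       E_Y_in_complex=-198.0)
    assert be_relax(rec) == pytest.approx(15.0)
    assert be_rigid(rec) == pytest.approx(18.0)


def test_missing_fields_raise_undefined_quantity():
    rec = EnergyRecord("X-h", "Y-h", "p", E_complex=-1.0,
                       E_X_isolated=0.0, E_Y_isolated=0.0)
    with pytest.raises(UndefinedQuantityError):
        be_relax(rec)
    with pytest.raises(UndefinedQuantityError):
        be_rigid(rec)


@settings(max_examples=100, derandomize=True)
@given(st.floats(-500, 0), st.floats(-500, 0), st.floats(-1000, 0),
       st.floats(0, 10), st.floats(0, 10))
def test_rigid_at_least_relax_when_fragments_destabilised(ex, ey, ecp, dx, dy):
    """Frozen in-complex fragments lie above the relaxed monomers, so
    BE_rigid >= BE_relax."""
    rec = EnergyRecord("X-h", "Y-h", "p", E_complex=ecp,
                       E_X_isolated=ex, E_Y_isolated=ey, E_complex_CP=ecp,
                       E_X_in_complex=ex + dx, E_Y_in_complex=ey + dy)
    assert be_rigid(rec) >= be_relax(rec) - 1e-9


# ---------------------------------------------------------------------------
# surrogate scorer

def _alignment_with_contacts(x, y, n):
    return [a for a in enumerate_alignments(x.pattern, y.pattern)
            if a.n_contacts == n][0]


def test_triple_donor_acceptor_pose_hand_sum():
    """3 primary pyridinic bonds + 4 attractive diagonal cross-terms."""
    ddd, aaa = _group("HHH", "hhh"), _group("NNN", "hhh")
    a3 = _alignment_with_contacts(ddd, aaa, 3)
    assert surrogate_pair_energy(ddd, aaa, a3) == pytest.approx(3 * 6.0 + 4 * 1.5)


def test_acceptor_homo_pair_hand_sum():
    """2 lone-pair repulsions + 2 repulsive cross-terms."""
    aa = _group("NN")
    a2 = _alignment_with_contacts(aa, aa, 2)
    assert surrogate_pair_energy(aa, aa, a2) == pytest.approx(-(2 * 1.0) - 2 * 1.5)


def test_planar_donor_homo_pair_binds_nowhere():
    dd = _group("HH", planarity=1.0)
    energies = [surrogate_pair_energy(dd, dd, a)
                for a in enumerate_alignments(dd.pattern, dd.pattern)]
    assert max(energies) == 0.0  # single-contact register: no terms at all
    assert all(e <= 0.0 for e in energies)


def test_pyramidal_donor_homo_pair_binds():
    dd = _group("HH", planarity=0.0)
    energies = [surrogate_pair_energy(dd, dd, a)
                for a in enumerate_alignments(dd.pattern, dd.pattern)]
    assert max(energies) > 0.0


def test_keto_weaker_than_pyridinic():
    d = _group("H")
    assert surrogate_pair_energy(d, _group("O"), Alignment(False, 0, ((0, 0),))) \
        == pytest.approx(5.0)
    assert surrogate_pair_energy(d, _group("N"), Alignment(False, 0, ((0, 0),))) \
        == pytest.approx(6.0)


def test_surrogate_symmetric_including_noise():
    x, y = parse_code("HHN-h"), parse_code("NO-h")
    params = SurrogateParams(sigma_noise=0.7, seed=11)
    for a in enumerate_alignments(x.pattern, y.pattern):
        e_xy = surrogate_pair_energy(x, y, a, params)
        e_yx = surrogate_pair_energy(y, x, mirror(a, 3, 2), params)
        assert e_xy == pytest.approx(e_yx, abs=1e-12)


def test_noise_reproducible_and_seed_sensitive():
    x, y = parse_code("HH-h"), parse_code("NN-h")
    a = enumerate_alignments(x.pattern, y.pattern)[0]
    p1 = SurrogateParams(sigma_noise=0.5, seed=1)
    assert surrogate_pair_energy(x, y, a, p1) == \
        surrogate_pair_energy(x, y, a, p1)
    p2 = SurrogateParams(sigma_noise=0.5, seed=2)
    assert surrogate_pair_energy(x, y, a, p1) != \
        surrogate_pair_energy(x, y, a, p2)


def test_param_validation():
    with pytest.raises(ValueError):
        SurrogateParams(P_N=-1.0)
    with pytest.raises(ValueError):
        SurrogateParams(beta=1.5)


# ---------------------------------------------------------------------------
# best-pose selection

def _pose(flip, shift, contacts):
    return PairPose(alignment=Alignment(flip, shift, contacts))


def test_tie_break_prefers_fewer_contacts_then_lowest_register():
    poses = [
        (_pose(False, 0, ((0, 2), (1, 1), (2, 0))), 8.0),
        (_pose(True, 1, ((1, 0), (2, 1))), 8.0),
        (_pose(False, 1, ((1, 2), (2, 1))), 8.0),
        (_pose(False, -2, ((0, 0),)), 3.0),
    ]
    best, energy = select_best_pose(poses)
    assert energy == 8.0
    assert best.alignment == Alignment(False, 1, ((1, 2), (2, 1)))


def test_single_pose_returned():
    poses = [(_pose(False, 0, ((0, 0),)), -1.0)]
    assert select_best_pose(poses)[0] is poses[0][0]


def test_planarity_filter_falls_back_to_next_best():
    poses = [(_pose(False, s, ((max(0, s), 0),)), float(s)) for s in range(4)]
    reject_best = lambda pose: pose.alignment.shift != 3  # noqa: E731
    best, energy = select_best_pose(poses, planarity_ok=reject_best)
    assert energy == 2.0
    with pytest.raises(NoPlanarPoseError) as err:
        select_best_pose(poses, planarity_ok=lambda p: False)
    assert len(err.value.rejected) == 4


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 20), st.booleans()),
                min_size=1, max_size=12))
def test_selection_agrees_with_filter_then_argmax_oracle(spec):
    poses = []
    for k, (e10, planar) in enumerate(spec):
        pose = _pose(bool(k % 2), k, ((0, 0),))
        pose.collided = not planar
        poses.append((pose, e10 / 10.0))
    ok = lambda p: not p.collided  # noqa: E731
    passing = [(p, e) for p, e in poses if ok(p)]
    if not passing:
        with pytest.raises(NoPlanarPoseError):
            select_best_pose(poses, planarity_ok=ok)
        return
    best, energy = select_best_pose(poses, planarity_ok=ok)
    assert energy == max(e for _, e in passing)
    assert not best.collided


# ---------------------------------------------------------------------------
# energy tables

def _write(tmp_path, text, name="table.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


def test_minimal_table_and_round_trip(tmp_path):
    path = _write(tmp_path, (
        "group_x,group_y,pose_id,E_complex,E_X_isolated,E_Y_isolated,note\n"
        "HH-h,NN-h,f0s0,-30.0,-10.0,-12.0,ok\n"
    ))
    records = read_energy_table(path)
    assert len(records) == 1
    assert records[0].extra["note"] == "ok"
    out = tmp_path / "back.csv"
    write_energy_table(records, out)
    again = read_energy_table(out)
    assert again[0].E_complex == records[0].E_complex
    assert again[0].extra["note"] == "ok"


def test_hartree_conversion(tmp_path):
    path = _write(tmp_path, (
        "group_x,group_y,pose_id,E_complex,E_X_isolated,E_Y_isolated\n"
        "X-h,Y-h,p,-1.0,-0.4,-0.5\n"
    ))
    (rec,) = read_energy_table(path, unit="hartree")
    assert rec.E_complex == pytest.approx(-HARTREE_TO_KCAL)
    assert rec.E_X_isolated == pytest.approx(-0.4 * HARTREE_TO_KCAL)


def test_per_row_unit_column(tmp_path):
    path = _write(tmp_path, (
        "group_x,group_y,pose_id,E_complex,E_X_isolated,E_Y_isolated,unit\n"
        "X-h,Y-h,p1,-10.0,-4.0,-5.0,kcal/mol\n"
        "X-h,Y-h,p2,-1.0,-0.4,-0.5,hartree\n"
    ))
    records = read_energy_table(path)
    assert records[0].E_complex == pytest.approx(-10.0)
    assert records[1].E_complex == pytest.approx(-HARTREE_TO_KCAL)


def test_missing_column_and_bad_cell(tmp_path):
    with pytest.raises(EnergyTableError, match="missing required"):
        read_energy_table(_write(tmp_path,
                                 "group_x,group_y,pose_id,E_complex\nX,Y,p,-1\n"))
    with pytest.raises(EnergyTableError, match="row 2"):
        read_energy_table(_write(tmp_path, (
            "group_x,group_y,pose_id,E_complex,E_X_isolated,E_Y_isolated\n"
            "X-h,Y-h,p,oops,-1.0,-1.0\n"), "bad.csv"))


def test_conflicting_duplicates_name_both_rows(tmp_path):
    path = _write(tmp_path, (
        "group_x,group_y,pose_id,E_complex,E_X_isolated,E_Y_isolated\n"
        "X-h,Y-h,p,-10.0,-4.0,-5.0\n"
        "X-h,Y-h,p,-11.0,-4.0,-5.0\n"
    ))
    with pytest.raises(EnergyTableError, match="rows 2 and 3"):
        read_energy_table(path)


def test_identical_duplicates_collapse(tmp_path):
    path = _write(tmp_path, (
        "group_x,group_y,pose_id,E_complex,E_X_isolated,E_Y_isolated\n"
        "X-h,Y-h,p,-10.0,-4.0,-5.0\n"
        "X-h,Y-h,p,-10.0,-4.0,-5.0\n"
    ))
    assert len(read_energy_table(path)) == 1
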