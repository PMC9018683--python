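import numpy as np
import pytest
from hypothesis import given, strategies as st

from ssnmrpipe import synthetic
from ssnmrpipe.model import StructureBundle, StructureModel
from ssnmrpipe.restraints import (DistanceRestraint, RestraintSet,
                                  TorsionRestraint, classify,
                                  compute_violations, dihedral,
                                  per_residue_counts, read_nmrstar,
                                  read_talos, read_tsv, read_xplor, tabulate,
                                  to_bounds, write_tsv, write_xplor)


class TestClassify:
    @pytest.mark.parametrize("sep,cat", [
        (0, "intra"), (1, "sequential"), (2, "medium"), (3, "medium"),
        (4, "medium"), (5, "long"), (7, "long"), (100, "long")])
    def test_partition(self, sep, cat):
        assert classify(sep) == cat

    def test_boundary_switch(self):
        # the printed table leaves |i-j|=4 unassigned; medium_max moves it
        assert classify(4, medium_max=3) == "long"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify(-1)

    @given(sep=st.integers(0, 500))
    def test_total(self, sep):
        assert classify(sep) in ("intra", "sequential", "medium", "long")


class TestToBounds:
    def test_intra(self):
        assert to_bounds("intra-residue") == (1.5, 6.5)

    def test_inter(self):
        assert to_bounds("inter-residue") == (2.0, 7.2)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            to_bounds("weird")

    def test_lower_below_upper(self):
        for kind in ("intra-residue", "inter-residue"):
            lo, hi = to_bounds(kind)
            assert lo < hi


def _restraint(i, j, ambiguous=False, atoms=("CA", "CB")):
    opts = [((i, atoms[0]), (j, atoms[1]))]
    if ambiguous:
        opts.append(((i, atoms[0]), (j + 10, atoms[1])))
    return DistanceRestraint(options=tuple(opts), lower=2.0, upper=7.2)


class TestTabulate:
    def test_known_categories(self):
        rset = RestraintSet([
            _restraint(5, 5), _restraint(5, 6), _restraint(5, 8),
            _restraint(5, 30), _restraint(5, 40, ambiguous=True)])
        table = tabulate(rset)
        by_cat = dict(zip(table.category, table.total))
        assert by_cat["intra"] == 1
        assert by_cat["sequential"] == 1
        assert by_cat["medium"] == 1
        assert by_cat["long"] == 1
        assert by_cat["ambiguous"] == 1
        assert by_cat["total_unambiguous"] == 4

    def test_empty_all_zero(self):
        table = tabulate(RestraintSet([]))
        assert (table.total == 0).all()

    def test_category_conservation(self):
        rset = RestraintSet([_restraint(1, 1 + k) for k in range(20)])
        table = tabulate(rset)
        by_cat = dict(zip(table.category, table.total))
        assert (by_cat["intra"] + by_cat["sequential"] + by_cat["medium"]
                + by_cat["long"]) == by_cat["total_unambiguous"]

    def test_nc_split(self):
        rset = RestraintSet([
            DistanceRestraint(options=(((1, "N"), (7, "CA")),),
                              lower=2.0, upper=7.2)])
        table = tabulate(rset)
        assert table[table.category == "long"].NC.iloc[0] == 1


class TestPerResidueCounts:
    def test_single_restraint(self):
        counts = per_residue_counts(RestraintSet([_restraint(5, 80)]))
        assert counts == {5: 1, 80: 1}

    def test_empty(self):
        assert per_residue_counts(RestraintSet([])) == {}

    def test_total_conservation(self):
        rset = RestraintSet([_restraint(i, i + 5) for i in range(1, 31)])
        counts = per_residue_counts(rset)
        assert sum(counts.values()) == 2 * len(rset)

    def test_ambiguous_excluded_by_default(self):
        rset = RestraintSet([_restraint(5, 80, ambiguous=True)])
        assert per_residue_counts(rset) == {}
        assert per_residue_counts(rset, include_ambiguous=True) == {5: 1, 80: 1}


def _line_model(distances):
    """Residues on the x axis: residue k's CA at x = cumulative distance."""
    xs = np.concatenate([[0.0], np.cumsum(distances)])
    coords = np.array([[x, 0.0, 0.0] for x in xs])
    n = len(xs)
    return StructureModel(list(range(1, n + 1)), ["ALA"] * n, ["CA"] * n,
                          ["C"] * n, coords)


class TestComputeViolations:
    def test_violation_arithmetic(self):
        # distance 7.1, upper 6.5 -> violation 0.6
        m = _line_model([7.1])
        r = DistanceRestraint(options=(((1, "CA"), (2, "CA")),),
                              lower=1.5, upper=6.5)
        rep = compute_violations(StructureBundle([m]), RestraintSet([r]))
        assert rep.max_distance == pytest.approx(0.6)
        assert rep.distance_mean == pytest.approx(0.6)

    def test_within_bounds_zero(self):
        m = _line_model([5.0])
        r = DistanceRestraint(options=(((1, "CA"), (2, "CA")),),
                              lower=1.5, upper=6.5)
        rep = compute_violations(StructureBundle([m]), RestraintSet([r]))
        assert rep.max_distance == 0.0

    def test_lower_bound_violation(self):
        m = _line_model([1.0])
        r = DistanceRestraint(options=(((1, "CA"), (2, "CA")),),
                              lower=1.5, upper=6.5)
        rep = compute_violations(StructureBundle([m]), RestraintSet([r]))
        assert rep.max_distance == pytest.approx(0.5)

    def test_r6_pooling_relieves_group(self):
        # one member within bounds dominates the r^-6 sum
        m = _line_model([5.0, 15.0])
        r = DistanceRestraint(options=(((1, "CA"), (2, "CA")),
                                       ((1, "CA"), (3, "CA"))),
                              lower=1.5, upper=6.5)
        rep = compute_violations(StructureBundle([m]), RestraintSet([r]))
        assert rep.max_distance < 0.01

    def test_zero_on_satisfying_bundle(self, uniform):
        from ssnmrpipe.assignment import assign_peaklist
        m = synthetic.make_helix_model(25, seed=51)
        stab = synthetic.make_shift_table(m, seed=52)
        peaks, _ = synthetic.simulate_peaklist(m, stab, uniform, r_max=6.5,
                                               shift_noise=0.0, seed=53)
        res = assign_peaklist(peaks, stab, uniform, homolog=m)
        bundle = synthetic.perturb_bundle(m, 3, 0.0, seed=54)
        rep = compute_violations(bundle, res.restraints)
        assert rep.max_distance == 0.0

    def test_unresolvable_atom_lists_selector(self):
        m = _line_model([5.0])
        r = DistanceRestraint(options=(((1, "CA"), (9, "XX")),),
                              lower=1.5, upper=6.5)
        with pytest.raises(KeyError, match="9/XX"):
            compute_violations(StructureBundle([m]), RestraintSet([r]))

    def test_torsion_violation(self, helix20):
        from ssnmrpipe.restraints import backbone_torsion
        phi5 = backbone_torsion(helix20, 5, "phi")
        tors = [TorsionRestraint(5, "phi", center=float(phi5),
                                 half_width=5.0),
                TorsionRestraint(5, "phi",
                                 center=float(((phi5 + 30 + 180) % 360) - 180),
                                 half_width=5.0)]
        rep = compute_violations(StructureBundle([helix20]),
                                 RestraintSet([]), tors)
        assert rep.max_torsion == pytest.approx(25.0, abs=1e-6)


class TestDihedral:
    def test_planar_cis_zero(self):
        assert dihedral([1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]) == \
            pytest.approx(0.0, abs=1e-9)

    def test_right_angle(self):
        val = dihedral([1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 1])
        assert abs(abs(val) - 45.0) < 1e-9


class TestRoundTrips:
    def _sample_set(self):
        return RestraintSet([
            DistanceRestraint(options=(((5, "CA"), (9, "CB")),),
                              lower=2.0, upper=7.2, experiment="CORD",
                              peak_ids=(3, 7)),
            DistanceRestraint(options=(((1, "CA"), (1, "CB")),),
                              lower=1.5, upper=6.5, experiment="CORD"),
            DistanceRestraint(options=(((2, "CA"), (8, "CB")),
                                       ((2, "CA"), (12, "CB"))),
                              lower=2.0, upper=7.2, experiment="PAIN-CP"),
        ])

    def test_tsv_round_trip_identity(self, tmp_path):
        rset = self._sample_set()
        p = tmp_path / "r.tsv"
        write_tsv(rset, p)
        back = read_tsv(p)
        assert len(back) == len(rset)
        for a, b in zip(rset, back):
            assert a == b

    def test_xplor_bound_algebra(self, tmp_path):
        rset = RestraintSet([DistanceRestraint(
            options=(((1, "CA"), (1, "CB")),), lower=1.5, upper=6.5)])
        p = tmp_path / "r.tbl"
        write_xplor(rset, p)
        line = p.read_text().strip()
        nums = [float(x) for x in line.split()[-3:]]
        assert nums[0] - nums[1] == pytest.approx(1.5)
        assert nums[0] + nums[2] == pytest.approx(6.5)

    def test_xplor_round_trip_bounds_and_groups(self, tmp_path):
        rset = self._sample_set()
        p = tmp_path / "r.tbl"
        write_xplor(rset, p)
        back = read_xplor(p)
        assert len(back) == 3
        for a, b in zip(rset, back):
            assert a.options == b.options
            assert a.lower == pytest.approx(b.lower)
            assert a.upper == pytest.approx(b.upper)

    def test_xplor_write_bit_stable(self, tmp_path):
        rset = self._sample_set()
        p1, p2 = tmp_path / "a.tbl", tmp_path / "b.tbl"
        write_xplor(rset, p1)
        write_xplor(rset, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_xplor_parse_error_has_line(self, tmp_path):
        p = tmp_path / "bad.tbl"
        p.write_text("assign (resid 1 and name CA) oops\n")
        with pytest.raises(ValueError, match=":1"):
            read_xplor(p)


STAR_FIXTURE = """\
data_synthetic

save_distance_constraints
   loop_
      _Gen_dist_constraint.ID
      _Gen_dist_constraint.Comp_index_ID_1
      _Gen_dist_constraint.Atom_ID_1
      _Gen_dist_constraint.Comp_index_ID_2
      _Gen_dist_constraint.Atom_ID_2
      _Gen_dist_constraint.Distance_lower_bound_val
      _Gen_dist_constraint.Distance_upper_bound_val
      1 5 CA 9 CB 2.0 7.2
      2 1 CA 1 CB 1.5 6.5
      3 2 CA 8 CB 2.0 7.2
      3 2 CA 12 CB 2.0 7.2
   stop_
save_

save_torsion_constraints
   loop_
      _Torsion_angle_constraint.ID
      _Torsion_angle_constraint.Torsion_angle_name
      _Torsion_angle_constraint.Comp_index_ID_2
      _Torsion_angle_constraint.Angle_lower_bound_val
      _Torsion_angle_constraint.Angle_upper_bound_val
      1 PHI 5 -80.0 -40.0
      2 PSI 5 -60.0 -20.0
      3 CHI1 5 -60.0 -20.0
   stop_
save_
"""


class TestNmrStar:
    def test_distance_rows(self, tmp_path):
        p = tmp_path / "r.str"
        p.write_text(STAR_FIXTURE)
        rset, torsions = read_nmrstar(p)
        assert len(rset) == 3
        ambig = [r for r in rset if r.ambiguous]
        assert len(ambig) == 1
        assert len(ambig[0].options) == 2

    def test_torsion_rows_phi_psi_only(self, tmp_path):
        p = tmp_path / "r.str"
        p.write_text(STAR_FIXTURE)
        _, torsions = read_nmrstar(p)
        assert len(torsions) == 2
        phi = torsions[0]
        assert phi.angle == "phi"
        assert phi.center == pytest.approx(-60.0)
        assert phi.half_width == pytest.approx(20.0)


TALOS_FIXTURE = """\
REMARK TALOS-style prediction table
DATA FIRST_RESID 1
VARS  RESID RESNAME PHI PSI DPHI DPSI DIST S2 COUNT CLASS
FORMAT %4d %s %8.3f %8.3f %8.3f %8.3f %8.3f %5.3f %2d %s
   2 A  -63.000  -42.000   12.0   15.0 0.0 0.9 10 Good
   3 L  -70.000  -35.000    0.0    8.0 0.0 0.9 10 Strong
   4 S 9999.000 9999.000    0.0    0.0 0.0 0.0  0 None
"""


class TestTalos:
    def test_rows_and_half_widths(self, tmp_path):
        p = tmp_path / "pred.tab"
        p.write_text(TALOS_FIXTURE)
        tors = read_talos(p)
        # residue 4 has no prediction; residue 3 DPHI=0 falls back to 20
        assert len(tors) == 4
        by_key = {(t.res_index, t.angle): t for t in tors}
        assert by_key[(2, "phi")].half_width == pytest.approx(12.0)
        assert by_key[(3, "phi")].half_width == pytest.approx(20.0)
        assert (4, "phi") not in by_key

    def test_missing_vars(self, tmp_path):
        p = tmp_path / "bad.tab"
        p.write_text("1 A -60 -40\n")
        with pytest.raises(ValueError, match="VARS"):
            read_talos(p)
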