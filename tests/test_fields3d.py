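"""CoMFA/CoMSIA field computation, field PLS and contour extraction."""

import numpy as np
import pytest

from pepqsar import fields3d, synthdata, validation
from pepqsar.fields3d import (
    ComfaProbe,
    ComsiaProbe,
    Grid3D,
    Structure3D,
    build_grid,
    column_filter,
    comfa_fields,
    comfa_field_matrix,
    comsia_fields,
    comsia_field_matrix,
    contour_map,
    fit_field_pls,
)


def single_atom(x=0.0, y=0.0, z=0.0, charge=0.0, radius=1.7, **weights):
    n = 1
    return Structure3D(
        elements=("C",),
        coords=np.array([[x, y, z]]),
        charges=np.array([float(charge)]),
        radii=np.array([float(radius)]),
        lj_epsilon=np.array([0.107]),
        hydrophobic=np.array([weights.get("hydrophobic", 0.0)]),
        donor=np.array([weights.get("donor", 0.0)]),
        acceptor=np.array([weights.get("acceptor", 0.0)]),
        mol_id="m",
    )


def point_grid(*xyz):
    return Grid3D(origin=np.asarray(xyz, dtype=float), spacing=1.0, shape=(1, 1, 1))


class TestGrid:
    def test_single_atom_counts(self):
        g = build_grid([single_atom()], spacing=2.0, margin=4.0)
        assert g.shape == (5, 5, 5)
        assert g.n_points == 125

    def test_encloses_all_structures(self):
        a = single_atom(-3.0, 0, 0)
        b = single_atom(7.0, 2.0, -1.0)
        g = build_grid([a, b], spacing=2.0, margin=4.0)
        pts = g.points()
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        coords = np.vstack([a.coords, b.coords])
        assert (lo <= coords.min(axis=0)).all()
        assert (hi >= coords.max(axis=0)).all()

    def test_zero_spacing_rejected(self):
        with pytest.raises(ValueError):
            build_grid([single_atom()], spacing=0.0)

    def test_empty_structure_list(self):
        with pytest.raises(ValueError):
            build_grid([])


class TestComfaFields:
    def test_far_field_decay(self):
        s = single_atom(charge=0.0)
        steric, electro = comfa_fields(s, point_grid(50.0, 0, 0))
        assert abs(steric[0]) < 1e-6
        assert electro[0] == 0.0

    def test_steric_clamps_on_close_approach(self):
        s = single_atom()
        steric, _ = comfa_fields(s, point_grid(0.1, 0, 0))
        assert steric[0] == pytest.approx(30.0)

    def test_atom_on_grid_point_clamped_not_error(self):
        s = single_atom()
        steric, electro = comfa_fields(s, point_grid(0.0, 0, 0))
        assert steric[0] == 30.0

    def test_coulomb_closed_form(self):
        s = single_atom(charge=1.0)
        _, e_333 = comfa_fields(s, point_grid(3.33, 0, 0))
        assert e_333[0] == pytest.approx(332.06 / 3.33**2, abs=1e-9)
        assert e_333[0] < 30.0  # retained, not clamped
        _, e_30 = comfa_fields(s, point_grid(3.0, 0, 0))
        assert e_30[0] == 30.0  # 36.9 truncated

    def test_electrostatic_sign(self):
        s = single_atom(charge=0.2)
        _, electro = comfa_fields(s, point_grid(4.0, 0, 0))
        assert electro[0] > 0  # positive probe near positive charge

    def test_steric_well_depth(self):
        # at r = R_ip the LJ term is exactly -eps_ip
        s = single_atom(radius=1.7)
        R = 1.7 + 1.52
        steric, _ = comfa_fields(s, point_grid(R, 0, 0))
        assert steric[0] == pytest.approx(-np.sqrt(0.107 * 0.107), abs=1e-9)

    def test_all_values_clamped(self, rng):
        structs, _, _ = synthdata.gen_toy_structures(5, seed=1)
        g = build_grid(structs)
        for s in structs:
            steric, electro = comfa_fields(s, g)
            assert steric.max() <= 30.0 and steric.min() >= -30.0
            assert electro.max() <= 30.0 and electro.min() >= -30.0

    def test_translation_invariance(self):
        structs, _, _ = synthdata.gen_toy_structures(3, seed=2)
        g = build_grid(structs)
        shift = np.array([13.7, -4.2, 8.9])
        for s in structs:
            ref_s, ref_e = comfa_fields(s, g)
            new_s, new_e = comfa_fields(s.translated(shift), g.translated(shift))
            assert np.abs(ref_s - new_s).max() < 1e-9
            assert np.abs(ref_e - new_e).max() < 1e-9


class TestComsiaFields:
    def test_value_at_zero_distance(self):
        s = single_atom(charge=1.0, hydrophobic=1.0, donor=0.7, acceptor=0.3)
        g = point_grid(0.0, 0, 0)
        out = comsia_fields(s, g, properties=("hydrophobic", "donor", "acceptor"))
        assert out["hydrophobic"][0] == pytest.approx(-1.0)  # -w_probe * w_atom
        assert out["donor"][0] == pytest.approx(-0.7)
        assert out["acceptor"][0] == pytest.approx(-0.3)

    def test_steric_probe_weight_is_volume(self):
        s = single_atom(radius=1.5)
        out = comsia_fields(s, point_grid(0.0, 0, 0), properties=("steric",))
        assert out["steric"][0] == pytest.approx(-(2.0**3) * 1.5**3)

    def test_far_field_vanishes(self):
        s = single_atom(hydrophobic=1.0)
        out = comsia_fields(s, point_grid(40.0, 0, 0), properties=("hydrophobic",))
        assert abs(out["hydrophobic"][0]) < 1e-12

    def test_two_symmetric_atoms_sum(self):
        two = Structure3D(
            elements=("C", "C"),
            coords=np.array([[-2.0, 0, 0], [2.0, 0, 0]]),
            charges=np.zeros(2),
            radii=np.full(2, 1.7),
            lj_epsilon=np.full(2, 0.107),
            hydrophobic=np.array([0.6, 0.6]),
            donor=np.zeros(2),
            acceptor=np.zeros(2),
        )
        one = single_atom(2.0, 0, 0, hydrophobic=0.6)
        g = point_grid(0.0, 0, 0)
        v2 = comsia_fields(two, g, properties=("hydrophobic",))["hydrophobic"][0]
        v1 = comsia_fields(one, g, properties=("hydrophobic",))["hydrophobic"][0]
        assert v2 == pytest.approx(2 * v1, abs=1e-10)
        # direct summation oracle: both atoms at distance 2 A
        direct = -sum(1.0 * 0.6 * np.exp(-0.3 * 2.0**2) for _ in range(2))
        assert v2 == pytest.approx(direct, abs=1e-10)

    def test_missing_property_weights_error(self):
        s = Structure3D(
            elements=("C",),
            coords=np.zeros((1, 3)),
            charges=np.zeros(1),
            radii=np.ones(1),
            lj_epsilon=np.ones(1) * 0.1,
        )
        with pytest.raises(ValueError, match="hydrophobic"):
            comsia_fields(s, point_grid(0, 0, 0), properties=("hydrophobic",))

    def test_translation_invariance(self):
        structs, _, _ = synthdata.gen_toy_structures(2, seed=3)
        g = build_grid(structs)
        shift = np.array([-7.0, 3.3, 1.1])
        for s in structs:
            ref = comsia_fields(s, g)
            new = comsia_fields(s.translated(shift), g.translated(shift))
            for prop in ref:
                assert np.abs(ref[prop] - new[prop]).max() < 1e-9


class TestFieldMatrix:
    def test_clash_electro_substitution(self):
        # molecule B has an atom on the first grid point -> steric clamps
        # there and B's electrostatic entry becomes the mean of the others
        g = Grid3D(origin=np.zeros(3), spacing=2.0, shape=(2, 1, 1))
        a = single_atom(10.0, 0, 0, charge=0.5)
        b = single_atom(0.0, 0, 0, charge=0.5)
        c = single_atom(8.0, 0, 0, charge=-0.5)
        fm = comfa_field_matrix([a, b, c], grid=g)
        e_block = fm.field_block("electrostatic")
        electro = fm.values[:, e_block]
        assert fm.electro_substituted[1, 0]
        assert electro[1, 0] == pytest.approx((electro[0, 0] + electro[2, 0]) / 2)

    def test_column_filter_hand_case(self):
        vals = np.array(
            [
                [0.0, 1.0, 5.0],
                [0.0, 2.0, -5.0],
                [0.0, 3.0, 5.0],
            ]
        )
        g = Grid3D(origin=np.zeros(3), spacing=1.0, shape=(3, 1, 1))
        fm = fields3d.FieldMatrix(
            values=vals,
            fields=("steric",),
            grid=g,
            mol_ids=("a", "b", "c"),
            kept=np.ones(3, bool),
            column_field=np.array(["steric"] * 3),
            column_point=np.arange(3),
        )
        out = column_filter(fm, 2.0)
        sd = vals.std(axis=0, ddof=1)
        np.testing.assert_array_equal(out.kept, sd >= 2.0)
        assert not out.kept[0]  # constant column dropped
        assert out.kept[2]  # sd > 2 kept

    def test_filter_all_dropped_error(self):
        structs = [single_atom(0, 0, 0), single_atom(0.1, 0, 0)]
        g = point_grid(30.0, 0, 0)
        fm = comfa_field_matrix(structs, grid=g)
        with pytest.raises(ValueError, match="lower the threshold"):
            column_filter(fm, 1e6)


class TestFieldPLS:
    def test_single_causal_column(self):
        # activity exactly linear in one steric column of an independent-
        # column matrix: at full rank the fit is exact and the causal field
        # takes the whole contribution
        rng = np.random.default_rng(4)
        vals = rng.normal(scale=4, size=(12, 8))
        g = Grid3D(origin=np.zeros(3), spacing=1.0, shape=(4, 1, 1))
        fm = fields3d.FieldMatrix(
            values=vals,
            fields=("steric", "electrostatic"),
            grid=g,
            mol_ids=tuple(f"m{i}" for i in range(12)),
            kept=np.ones(8, bool),
            column_field=np.array(["steric"] * 4 + ["electrostatic"] * 4),
            column_point=np.tile(np.arange(4), 2),
        )
        y = 1.0 + 0.5 * vals[:, 2]
        model = fit_field_pls(fm, y, nc=8)
        assert model.stats["r2_ncv"] > 0.999999
        assert model.contributions["steric"] > 0.99

    def test_identical_fields_split_contribution(self):
        # two fields carrying identical columns share the contribution 50/50
        rng = np.random.default_rng(8)
        vals = rng.normal(scale=5, size=(10, 4))
        vals = np.hstack([vals, vals])
        g = Grid3D(origin=np.zeros(3), spacing=1.0, shape=(4, 1, 1))
        fm = fields3d.FieldMatrix(
            values=vals,
            fields=("steric", "electrostatic"),
            grid=g,
            mol_ids=tuple(f"m{i}" for i in range(10)),
            kept=np.ones(8, bool),
            column_field=np.array(["steric"] * 4 + ["electrostatic"] * 4),
            column_point=np.tile(np.arange(4), 2),
        )
        y = vals[:, 0] - 0.3 * vals[:, 2] + rng.normal(scale=0.1, size=10)
        model = fit_field_pls(fm, y, nc=2)
        assert model.contributions["steric"] == pytest.approx(0.5, abs=1e-9)
        assert sum(model.contributions.values()) == pytest.approx(1.0, abs=1e-6)

    def test_loo_q2_matches_brute_force(self):
        structs, y, _ = synthdata.gen_toy_structures(10, seed=5)
        fm = column_filter(comfa_field_matrix(structs), 2.0)
        model = fit_field_pls(fm, y, nc=2)
        X = fm.kept_values()
        q2_ref, _ = validation.loo_q2(
            lambda Xa, ya: fields3d.fit_plsr(Xa, ya, 2).predict, X, y
        )
        assert model.stats["q2_cv"] == pytest.approx(q2_ref, abs=1e-8)

    def test_causal_steric_field_dominates(self):
        structs, y, truth = synthdata.gen_toy_structures(20, seed=42)
        fm = column_filter(comfa_field_matrix(structs), 2.0)
        model = fit_field_pls(fm, y, nc="auto", max_nc=5)
        assert truth["causal_field"] == "steric"
        assert model.contributions["steric"] > 0.7

    def test_exact_signal_high_r2(self):
        structs, y, _ = synthdata.gen_toy_structures(20, seed=42, noise_sd=0.0)
        fm = column_filter(comfa_field_matrix(structs), 2.0)
        model = fit_field_pls(fm, y, nc=6)
        assert model.stats["r2_ncv"] > 0.99


class TestContours:
    def _toy_model(self, v):
        """FieldPLSModel stub over one field whose StDev*Coeff values are v."""
        n = len(v)
        g = Grid3D(origin=np.zeros(3), spacing=1.0, shape=(n, 1, 1))
        fm = fields3d.FieldMatrix(
            values=np.zeros((4, n)),
            fields=("steric",),
            grid=g,
            mol_ids=("a", "b", "c", "d"),
            kept=np.ones(n, bool),
            column_field=np.array(["steric"] * n),
            column_point=np.arange(n),
        )
        return fields3d.FieldPLSModel(
            pls=None,
            fm=fm,
            n_components=1,
            contributions={"steric": 1.0},
            stdev_coeff=np.asarray(v, dtype=float),
            stats={},
        )

    def test_percentile_oracle(self):
        model = self._toy_model(np.arange(1.0, 11.0))
        cm = contour_map(model, "steric")
        # linear-interpolated percentiles of 1..10: 80th = 8.2, 20th = 2.8
        assert sorted(cm.favorable_values) == [9.0, 10.0]
        assert sorted(cm.unfavorable_values) == [1.0, 2.0]

    def test_single_column_sign_tiebreak(self):
        pos = contour_map(self._toy_model([2.5]), "steric")
        assert len(pos.favorable_values) == 1 and len(pos.unfavorable_values) == 0
        neg = contour_map(self._toy_model([-2.5]), "steric")
        assert len(neg.favorable_values) == 0 and len(neg.unfavorable_values) == 1

    def test_all_equal_positive(self):
        cm = contour_map(self._toy_model([1.5, 1.5, 1.5]), "steric")
        assert len(cm.favorable_values) == 3
        assert len(cm.unfavorable_values) == 0

    def test_disjoint(self):
        rng = np.random.default_rng(12)
        cm = contour_map(self._toy_model(rng.normal(size=40)), "steric")
        fav = {tuple(p) for p in cm.favorable_points}
        unfav = {tuple(p) for p in cm.unfavorable_points}
        assert not (fav & unfav)

    def test_absent_field(self):
        with pytest.raises(ValueError, match="absent"):
            contour_map(self._toy_model([1.0]), "hydrophobic")


class TestStructureIO:
    def test_xyzq_round_trip(self, tmp_path):
        path = tmp_path / "mol.xyzq"
        path.write_text(
            "# element x y z charge radius lj_epsilon hydrophobic donor acceptor\n"
            "C 0.0 0.0 0.0 0.25 1.70 0.107 0.5 0.1 0.2\n"
            "N 1.5 0.0 0.0 -0.40 1.55 0.095 0.0 0.9 0.3\n"
        )
        s = fields3d.read_xyzq(path)
        assert s.n_atoms == 2
        assert s.elements == ("C", "N")
        assert s.charges[1] == pytest.approx(-0.40)
        assert s.donor[1] == pytest.approx(0.9)

    def test_xyzq_element_table_fallback(self, tmp_path):
        path = tmp_path / "m.xyzq"
        path.write_text("S 0 0 0 0.1\n")
        s = fields3d.read_xyzq(path)
        assert s.radii[0] == pytest.approx(1.80)
        assert s.lj_epsilon[0] == pytest.approx(0.250)

    def test_pdb_with_occupancy_charges(self, tmp_path):
        pdb = tmp_path / "m.pdb"
        pdb.write_text(
            "ATOM      1  C1  LIG A   1       0.000   0.000   0.000  0.25 10.00           C\n"
            "ATOM      2  N1  LIG A   1       1.500   0.000   0.000 -0.40 20.00           N\n"
            "END\n"
        )
        s = fields3d.read_pdb(pdb, charge_from="occupancy")
        assert s.n_atoms == 2
        assert s.charges[0] == pytest.approx(0.25)
        assert s.elements[1] == "N"

    def test_superpose_recovers_rotation(self, rng):
        coords = rng.normal(size=(6, 3))
        ref = Structure3D(
            elements=("C",) * 6,
            coords=coords,
            charges=np.zeros(6),
            radii=np.full(6, 1.7),
            lj_epsilon=np.full(6, 0.107),
        )
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = fields3d.Structure3D(
            elements=ref.elements,
            coords=coords @ R.T + np.array([3.0, -1.0, 2.0]),
            charges=ref.charges,
            radii=ref.radii,
            lj_epsilon=ref.lj_epsilon,
        )
        back = fields3d.superpose(moved, ref, [(i, i) for i in range(6)])
        assert np.abs(back.coords - coords).max() < 1e-9
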