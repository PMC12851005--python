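"""Superposition, coordination, volumes and B-factor profile contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from rdtherm.geometry import (bfactor_profile, bfactor_to_msd,
                              coordination_stats, kabsch, msd_to_bfactor,
                              normalize_bfactors, protein_volume,
                              superpose_kabsch, unit_cell_volume)
from rdtherm.structure import Atom, StructureModel, UnitCell


def _model_from_coords(coords, names=None, resnames=None, bfactors=None,
                       temperature=100.0):
    atoms = []
    for i, c in enumerate(coords):
        atoms.append(Atom(
            serial=i + 1, name=(names[i] if names else "CA"),
            resname=(resnames[i] if resnames else "ALA"), chain="A",
            resseq=i + 1, x=float(c[0]), y=float(c[1]), z=float(c[2]),
            bfactor=(bfactors[i] if bfactors is not None else 20.0),
            element=(names[i][0] if names else "C")))
    return StructureModel(atoms=tuple(atoms), temperature=temperature)


TOY = np.array([[0.0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0],
                [0, 3.8, 1.5], [1.9, 1.9, 3.0]])


class TestKabsch:
    def test_self_superposition_is_identity(self):
        m = _model_from_coords(TOY)
        res = superpose_kabsch(m, m, ("*", "*", "CA"))
        assert res.rmsd < 1e-12
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)
        assert res.n_atoms == 5

    def test_rigid_motion_recovered(self):
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = TOY @ R.T + np.array([5.0, -3.0, 2.0])
        res = superpose_kabsch(_model_from_coords(moved),
                               _model_from_coords(TOY), ("*", "*", "CA"))
        assert res.rmsd < 1e-8

    @given(st.integers(0, 2 ** 32 - 1))
    def test_random_rigid_motions_have_zero_rmsd(self, seed):
        rng = np.random.default_rng(seed)
        R = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        moved = TOY @ R.T + rng.normal(size=3) * 10
        _, _, rmsd = kabsch(moved, TOY)
        assert rmsd < 1e-8

    def test_rotation_is_proper_orthonormal(self, rng):
        P = rng.normal(size=(6, 3))
        Q = rng.normal(size=(6, 3))
        R, _, _ = kabsch(P, Q)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-8)
        assert np.isclose(np.linalg.det(R), 1.0, atol=1e-8)

    def test_rmsd_after_not_above_rmsd_before(self, rng):
        for _ in range(5):
            P = TOY + rng.normal(scale=0.5, size=TOY.shape)
            before = np.sqrt(((P - TOY) ** 2).sum(axis=1).mean())
            _, _, after = kabsch(P, TOY)
            assert after <= before + 1e-12

    def test_matches_rotation_grid_oracle(self, rng):
        """Kabsch RMSD is the minimum over a fine grid of rotations."""
        P = TOY + rng.normal(scale=0.3, size=TOY.shape)
        _, _, rmsd = kabsch(P, TOY)
        angles = np.deg2rad(np.arange(0, 360, 9.0))
        betas = np.deg2rad(np.arange(0, 181, 9.0))
        grid = Rotation.from_euler(
            "ZYZ",
            np.array(np.meshgrid(angles, betas, angles)).reshape(3, -1).T
        ).as_matrix()
        P0 = P - P.mean(axis=0)
        Q0 = TOY - TOY.mean(axis=0)
        fits = np.einsum("rij,nj->rni", grid, P0) - Q0
        grid_min = np.sqrt((fits ** 2).sum(axis=2).mean(axis=1)).min()
        assert rmsd <= grid_min + 1e-9
        assert grid_min - rmsd < 0.15  # grid coarseness bound

    def test_matches_scipy_align_vectors(self, rng):
        P = TOY + rng.normal(scale=0.4, size=TOY.shape)
        R, _, rmsd = kabsch(P, TOY)
        rot, _ = Rotation.align_vectors(TOY - TOY.mean(axis=0),
                                        P - P.mean(axis=0))
        assert np.allclose(rot.as_matrix(), R, atol=1e-6)

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch(line, line + 1.0)

    def test_mismatched_correspondence_rejected(self):
        m5 = _model_from_coords(TOY)
        m4 = _model_from_coords(TOY[:4])
        with pytest.raises(ValueError, match="mismatch"):
            superpose_kabsch(m5, m4, ("*", "*", "CA"))


class TestCoordination:
    def test_tetrahedral_shell_mean(self):
        dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                        dtype=float)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        coords = np.vstack([[0.0, 0, 0], 2.34 * dirs])
        m = _model_from_coords(coords, names=["ZN", "SG", "SG", "SG", "SG"],
                               resnames=["ZN"] + ["CYS"] * 4)
        mean, d = coordination_stats(m, ("A", 1, "ZN"), ("A", "*", "SG"))
        assert mean == pytest.approx(2.34, abs=1e-12)
        assert np.allclose(d, 2.34)

    @pytest.mark.parametrize("ligand_coords,expected", [
        ([[0, 0, 1]], 1.0),
        ([[2, 0, 0], [0, 4, 0]], 3.0),
    ])
    def test_simple_means(self, ligand_coords, expected):
        coords = np.vstack([[0.0, 0, 0], np.array(ligand_coords, float)])
        names = ["ZN"] + ["SG"] * len(ligand_coords)
        m = _model_from_coords(coords, names=names,
                               resnames=["ZN"] + ["CYS"] * len(ligand_coords))
        mean, _ = coordination_stats(m, ("A", 1, "ZN"), ("A", "*", "SG"))
        assert mean == pytest.approx(expected)

    def test_ambiguous_center_rejected(self):
        m = _model_from_coords(TOY)
        with pytest.raises(ValueError):
            coordination_stats(m, ("A", "*", "CA"), ("A", 1, "CA"))


def _volume_triple_product(cell: UnitCell) -> float:
    ca, cb, cg = (math.cos(math.radians(v))
                  for v in (cell.alpha, cell.beta, cell.gamma))
    sg = math.sin(math.radians(cell.gamma))
    av = np.array([cell.a, 0, 0])
    bv = np.array([cell.b * cg, cell.b * sg, 0])
    cx = cell.c * cb
    cy = cell.c * (ca - cb * cg) / sg
    cz = cell.c * math.sqrt(max(0.0, 1 - cb ** 2 - ((ca - cb * cg) / sg) ** 2))
    return float(abs(np.dot(av, np.cross(bv, [cx, cy, cz]))))


class TestUnitCellVolume:
    def test_cubic(self):
        assert unit_cell_volume(UnitCell(10, 10, 10, 90, 90, 90)) == \
            pytest.approx(1000.0, rel=1e-12)

    def test_orthorhombic(self):
        assert unit_cell_volume(UnitCell(3, 5, 7, 90, 90, 90)) == \
            pytest.approx(105.0, rel=1e-12)

    def test_hexagonal_matches_triple_product(self):
        cell = UnitCell(10, 10, 10, 90, 90, 120)
        assert unit_cell_volume(cell) == \
            pytest.approx(_volume_triple_product(cell), rel=1e-12)

    @given(st.floats(5, 50), st.floats(5, 50), st.floats(5, 50),
           st.floats(60, 120), st.floats(60, 120), st.floats(60, 120))
    def test_random_cells_match_triple_product(self, a, b, c, al, be, ga):
        try:
            cell = UnitCell(a, b, c, al, be, ga)
        except ValueError:
            return  # geometrically impossible angle combination
        assert unit_cell_volume(cell) == \
            pytest.approx(_volume_triple_product(cell), rel=1e-9)

    def test_gemmi_agrees(self):
        gemmi = pytest.importorskip("gemmi")
        cell = UnitCell(34.0, 35.0, 44.0, 90.0, 95.5, 103.0)
        assert unit_cell_volume(cell) == pytest.approx(
            gemmi.UnitCell(34.0, 35.0, 44.0, 90.0, 95.5, 103.0).volume,
            rel=1e-9)


class TestProteinVolume:
    SPHERE_C = 4.0 / 3.0 * math.pi * 1.70 ** 3

    def test_single_carbon_sphere(self):
        m = _model_from_coords([[0.0, 0, 0]], names=["C"], resnames=["ALA"])
        assert protein_volume(m) == pytest.approx(self.SPHERE_C, rel=0.05)

    def test_disjoint_spheres_add(self):
        m = _model_from_coords([[0.0, 0, 0], [10.0, 0, 0]],
                               names=["C", "CA"], resnames=["ALA", "ALA"])
        assert protein_volume(m) == pytest.approx(2 * self.SPHERE_C, rel=0.05)

    def test_coincident_spheres_count_once(self):
        a = Atom(serial=1, name="C", resname="ALA", chain="A", resseq=1,
                 x=0, y=0, z=0, element="C")
        b = Atom(serial=2, name="CA", resname="ALA", chain="A", resseq=1,
                 x=0, y=0, z=0, element="C")
        m = StructureModel(atoms=(a, b), temperature=100.0)
        assert protein_volume(m) == pytest.approx(self.SPHERE_C, rel=0.05)

    def test_rigid_motion_invariance(self, model_100K):
        """On a protein-sized model, grid error averages below 1%."""
        R = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
        moved_atoms = tuple(
            a.__class__(**{**a.__dict__,
                           **dict(zip("xyz", (R @ a.coord) + [7.3, -2.1, 0.4]))})
            for a in model_100K.atoms)
        moved = StructureModel(atoms=moved_atoms,
                               temperature=model_100K.temperature)
        v1 = protein_volume(model_100K)
        v2 = protein_volume(moved)
        assert v2 == pytest.approx(v1, rel=0.01)

    def test_monotone_under_adding_atoms(self):
        v_small = protein_volume(_model_from_coords(TOY[:3]))
        v_big = protein_volume(_model_from_coords(TOY))
        assert v_big >= v_small

    def test_waters_and_hydrogens_excluded(self):
        atoms = (
            Atom(serial=1, name="C", resname="ALA", chain="A", resseq=1,
                 x=0, y=0, z=0, element="C"),
            Atom(serial=2, name="O", resname="HOH", chain="S", resseq=101,
                 x=20, y=0, z=0, element="O", record="HETATM"),
            Atom(serial=3, name="H1", resname="ALA", chain="A", resseq=1,
                 x=-20, y=0, z=0, element="H"),
        )
        m = StructureModel(atoms=atoms, temperature=100.0)
        assert protein_volume(m) == pytest.approx(self.SPHERE_C, rel=0.05)


class TestBFactors:
    def test_uniform_profile(self):
        m = _model_from_coords(TOY, bfactors=[20.0] * 5)
        prof = bfactor_profile(m)
        assert set(prof.values.values()) == {20.0}

    def test_hot_loop_residues_are_maxima(self):
        b = [20.0, 60.0, 60.0, 20.0, 20.0]
        prof = bfactor_profile(_model_from_coords(TOY, bfactors=b))
        hottest = sorted(prof.values, key=prof.values.get)[-2:]
        assert set(hottest) == {2, 3}

    def test_normalize_hand_computed_zscores(self):
        prof = bfactor_profile(_model_from_coords(
            TOY[:3], bfactors=[10.0, 20.0, 30.0]))
        z = normalize_bfactors(prof)
        vals = np.array(list(z.values.values()))
        expected = np.array([-1.0, 0.0, 1.0]) * math.sqrt(1.5)
        assert np.allclose(vals, expected, atol=1e-12)
        assert vals.mean() == pytest.approx(0.0, abs=1e-12)
        assert vals.std() == pytest.approx(1.0, abs=1e-12)

    def test_zero_spread_rejected(self):
        prof = bfactor_profile(_model_from_coords(TOY, bfactors=[20.0] * 5))
        with pytest.raises(ValueError, match="spread"):
            normalize_bfactors(prof)

    @given(st.floats(0.1, 10), st.floats(-5, 50))
    def test_affine_invariance(self, a, b):
        base = np.array([12.0, 18.0, 25.0, 40.0])
        prof1 = bfactor_profile(_model_from_coords(TOY[:4], bfactors=base))
        prof2 = bfactor_profile(_model_from_coords(
            TOY[:4], bfactors=np.maximum(a * base + b, 0.0)))
        if a * base.min() + b < 0:
            return
        z1 = list(normalize_bfactors(prof1).values.values())
        z2 = list(normalize_bfactors(prof2).values.values())
        assert np.allclose(z1, z2, atol=1e-9)

    def test_profile_mean_sd_contract_on_fixture(self, fixture_series):
        for m in fixture_series:
            z = normalize_bfactors(bfactor_profile(m))
            vals = np.array(list(z.values.values()))
            assert abs(vals.mean()) < 1e-12
            assert abs(vals.std() - 1.0) < 1e-12

    def test_msd_conversion_round_trip(self):
        assert msd_to_bfactor(bfactor_to_msd(25.0)) == pytest.approx(25.0)
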