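import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from aplkit import (
    count_contacts,
    make_toy_pmhc_pair,
    peptide_backbone_rmsd,
    read_structure,
    shrake_rupley_sasa,
    superpose,
    transform_model,
    write_structure,
)
from aplkit.structure import StructureModel, classify_orientation

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.40  0.00           C
END
"""


def atom_table(rows):
    return pd.DataFrame(
        rows,
        columns=["chain", "resnum", "resname", "atom", "element",
                 "x", "y", "z", "altloc", "occupancy"],
    )


def point_model(points_by_chain):
    rows = []
    for chain, pts in points_by_chain.items():
        for i, p in enumerate(pts):
            rows.append((chain, i + 1, "ALA", "CA", "C", *p, "", 1.0))
    return StructureModel(atoms=atom_table(rows))


class TestReadStructure:
    def test_minimal_two_atom_file(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        model = read_structure(path)
        assert len(model.atoms) == 2
        ca = model.atoms[model.atoms["atom"] == "CA"].iloc[0]
        assert ca["x"] == pytest.approx(11.639)

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        model = read_structure(path)
        assert len(model.atoms) == 1
        assert model.atoms.iloc[0]["altloc"] == "A"
        assert model.atoms.iloc[0]["x"] == 0.0

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(ValueError):
            read_structure(path)

    def test_write_read_round_trip(self, tmp_path):
        ref, _ = make_toy_pmhc_pair(seed=1)
        path = tmp_path / "toy.pdb"
        write_structure(ref, path)
        back = read_structure(path)
        assert len(back.atoms) == len(ref.atoms)
        np.testing.assert_allclose(
            back.coords(), ref.coords(), atol=1e-3
        )  # PDB format stores 3 decimals


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        rotation, translation, rmsd = superpose(pts, pts)
        assert rmsd < 1e-10
        np.testing.assert_allclose(rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([5.0, 0.0, 0.0])
        _, _, rmsd = superpose(moved, pts)
        assert rmsd < 1e-8

    def test_constructed_deviation_fixture_rmsd_quarter_angstrom(self):
        """Paired antiparallel displacements leave RMSD exactly 0.25 A."""
        ref = np.array(
            [
                [0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 0.0],
                [10.0, 10.0, 5.0], [0.0, 0.0, 4.0], [10.0, 0.0, 4.0],
                [3.0, 7.0, 2.0], [7.0, 3.0, 1.0],
            ]
        )
        disp = np.zeros_like(ref)
        disp[0], disp[4] = [0, 0, 0.3], [0, 0, -0.3]
        disp[1], disp[5] = [0, 0, 0.4], [0, 0, -0.4]
        rotation, _, rmsd = superpose(ref + disp, ref)
        np.testing.assert_allclose(rotation, np.eye(3), atol=1e-12)
        assert rmsd == pytest.approx(0.25, abs=1e-12)

    def test_matches_brute_force_rotation_grid(self):
        """Kabsch minimum agrees with a dense rotation-grid search."""
        rng = np.random.default_rng(7)
        ref = rng.normal(size=(5, 3))
        mob = ref + rng.normal(0.0, 0.2, size=(5, 3))
        _, _, kabsch_rmsd = superpose(mob, ref)
        ref_c = ref - ref.mean(axis=0)
        mob_c = mob - mob.mean(axis=0)
        step = 9.0
        angles = np.arange(0.0, 360.0, step)
        half = np.arange(0.0, 180.0 + step, step)
        best = np.inf
        for a in angles:
            for b in half:
                for c in angles:
                    rot = Rotation.from_euler("zyz", [a, b, c], degrees=True)
                    moved = mob_c @ rot.as_matrix().T
                    best = min(best, np.sqrt(np.mean(np.sum((moved - ref_c) ** 2, axis=1))))
        assert kabsch_rmsd <= best + 1e-9
        assert best - kabsch_rmsd < 0.1  # grid resolution slack

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)


class TestContacts:
    def test_threshold_and_strict_boundary(self):
        model = point_model(
            {"C": [(0.0, 0.0, 0.0)], "A": [(3.9, 0.0, 0.0), (4.0, 0.0, 0.0)]}
        )
        report = count_contacts(model, "C", "A", cutoff=4.0)
        assert report.contact_count == 1  # 4.0 A pair excluded: strict <

    def test_hand_built_distances(self):
        model = point_model(
            {"C": [(0.0, 0.0, 0.0)],
             "A": [(2.0, 0.0, 0.0), (0.0, 3.5, 0.0), (0.0, 0.0, 4.5)]}
        )
        report = count_contacts(model, "C", "A", cutoff=4.0)
        assert report.contact_count == 2
        assert all(d < 4.0 for *_, d in report.pairs)

    def test_symmetric_under_chain_swap(self):
        ref, _ = make_toy_pmhc_pair(seed=2)
        fwd = count_contacts(ref, "C", "A", cutoff=6.0)
        # swapping roles: peptide residues 1-10 all fall in the default range
        rev = count_contacts(ref, "A", "C", groove_residue_range=(1, 10), cutoff=6.0)
        assert fwd.contact_count == rev.contact_count

    def test_invariant_under_rigid_transform(self):
        ref, _ = make_toy_pmhc_pair(seed=3)
        rot = Rotation.from_euler("xyz", [10, 40, 70], degrees=True).as_matrix()
        moved = transform_model(ref, rot, np.array([1.0, -2.0, 3.0]))
        before = count_contacts(ref, "C", "A", cutoff=5.0).contact_count
        after = count_contacts(moved, "C", "A", cutoff=5.0).contact_count
        assert before == after

    def test_missing_chain_errors(self):
        ref, _ = make_toy_pmhc_pair(seed=4)
        with pytest.raises(ValueError):
            count_contacts(ref, "X", "A")


class TestBackboneRmsd:
    def test_self_comparison_is_zero(self):
        ref, _ = make_toy_pmhc_pair(seed=5)
        assert peptide_backbone_rmsd(ref, ref) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_is_zero(self):
        ref, moved = make_toy_pmhc_pair(seed=6, perturbation_sd=0.0)
        assert peptide_backbone_rmsd(ref, moved) == pytest.approx(0.0, abs=1e-8)

    def test_uniform_half_angstrom_shift(self):
        ref, _ = make_toy_pmhc_pair(seed=7)
        atoms = ref.atoms.copy()
        pep = atoms["chain"] == "C"
        atoms.loc[pep, "z"] += 0.5
        shifted = StructureModel(atoms=atoms)
        assert peptide_backbone_rmsd(ref, shifted) == pytest.approx(0.5, abs=1e-9)

    def test_unequal_peptides_rejected(self):
        ref, _ = make_toy_pmhc_pair(seed=8)
        truncated = StructureModel(
            atoms=ref.atoms[
                ~((ref.atoms["chain"] == "C") & (ref.atoms["resnum"] == 10))
            ].reset_index(drop=True)
        )
        with pytest.raises(ValueError):
            peptide_backbone_rmsd(ref, truncated)


class TestSasaAndOrientation:
    def test_isolated_carbon_closed_form(self):
        area = shrake_rupley_sasa(np.zeros((1, 3)), ["C"], n_points=960)[0]
        assert area == pytest.approx(4 * np.pi * 3.1**2, abs=0.5)

    def test_caged_atom_is_buried(self):
        # surround a carbon by a tight shell of neighbours: no probe access
        from aplkit.structure import _sphere_points

        shell = 2.5 * _sphere_points(80)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        areas = shrake_rupley_sasa(coords, ["C"] * len(coords), n_points=960)
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_sampling_convergence(self):
        rng = np.random.default_rng(12)
        coords = rng.normal(scale=3.0, size=(12, 3))
        elements = ["C", "N", "O"] * 4
        coarse = shrake_rupley_sasa(coords, elements, n_points=960).sum()
        fine = shrake_rupley_sasa(coords, elements, n_points=1920).sum()
        assert abs(fine - coarse) / fine < 0.005

    def test_against_independent_biotite_oracle(self):
        """Per-atom SASA matches biotite's Shrake-Rupley on a random cluster."""
        import biotite.structure as struc

        rng = np.random.default_rng(5)
        n = 20
        coords = rng.normal(scale=4.0, size=(n, 3))
        mine = shrake_rupley_sasa(coords, ["C"] * n, n_points=2000)
        arr = struc.AtomArray(n)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * n)
        arr.res_id = np.arange(1, n + 1)
        arr.atom_name = np.array(["CA"] * n)
        arr.res_name = np.array(["ALA"] * n)
        arr.chain_id = np.array(["A"] * n)
        theirs = struc.sasa(
            arr, probe_radius=1.4, point_number=2000,
            vdw_radii=np.full(n, 1.7),
        )
        np.testing.assert_allclose(mine, theirs, rtol=0.03, atol=0.5)

    def test_orientation_invariant_under_rigid_transform(self):
        ref, _ = make_toy_pmhc_pair(seed=9)
        rot = Rotation.from_euler("xyz", [15, 25, 35], degrees=True).as_matrix()
        moved = transform_model(ref, rot, np.array([8.0, -3.0, 2.0]))
        a = classify_orientation(ref, "C", ("A",), n_points=240)
        b = classify_orientation(moved, "C", ("A",), n_points=240)
        assert [r.classification for r in a] == [r.classification for r in b]

    def test_backbone_only_residues_not_classified(self):
        # toy residues carry no side-chain atoms
        ref, _ = make_toy_pmhc_pair(seed=10)
        records = classify_orientation(ref, "C", ("A",), n_points=120)
        assert len(records) == 10
        assert all(r.classification == "not-classified" for r in records)

    def test_exposed_vs_buried_split(self):
        # one leucine side-chain atom in open solvent, one caged by neighbours
        from aplkit.structure import _sphere_points

        rows = [
            ("C", 1, "LEU", "CA", "C", 0.0, 0.0, 0.0, "", 1.0),
            ("C", 1, "LEU", "CB", "C", 2.0, 0.0, 0.0, "", 1.0),
            ("C", 2, "LEU", "CA", "C", 20.0, 0.0, 0.0, "", 1.0),
            ("C", 2, "LEU", "CB", "C", 22.0, 0.0, 0.0, "", 1.0),
        ]
        for i, p in enumerate(2.5 * _sphere_points(60) + np.array([22.0, 0.0, 0.0])):
            rows.append(("A", i + 1, "ALA", "CA", "C", *p, "", 1.0))
        model = StructureModel(atoms=atom_table(rows))
        records = {r.resnum: r for r in classify_orientation(model, "C", ("A",))}
        assert records[1].classification == "exposed"
        assert records[2].classification == "buried"
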