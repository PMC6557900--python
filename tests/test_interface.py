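"""Structure reading, SASA/BSA kernels, distances and contacts."""

import math

import numpy as np
import pytest

from sh2bind.interface import (
    StructureModel,
    buried_surface_area,
    compute_sasa,
    list_contacts,
    read_structure,
    residue_distance,
)
from sh2bind.simulate import gen_toy_complex, write_structure

# minimal hand-written PDB with A/B altlocs on one atom (A at higher occupancy)
ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60 10.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.40 10.00           C
ATOM      3  CB  ALA A   1       0.000   1.500   0.000  1.00 10.00           C
END
"""


def mc_sasa_oracle(coords, radii, probe=1.4, n=200_000, seed=1234):
    """Monte-Carlo surface-point estimate of total SASA, independent of the
    deterministic spiral-lattice kernel."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, float)
    rad = np.asarray(radii, float) + probe
    total = 0.0
    for i in range(len(coords)):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = coords[i] + rad[i] * v
        exposed = np.ones(n, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            exposed &= np.sum((pts - coords[j]) ** 2, axis=1) > rad[j] ** 2
        total += exposed.mean() * 4 * math.pi * rad[i] ** 2
    return total


class TestReadStructure:
    def test_toy_round_trip_exact_coordinates(self, tmp_path):
        model = gen_toy_complex("hbond_pair")
        path = tmp_path / "toy.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert len(back) == len(model)
        np.testing.assert_allclose(back.coords(), model.coords(), atol=1e-3)

    def test_pdb_and_mmcif_agree(self, tmp_path):
        model = gen_toy_complex("touching_dimer")
        pdb, cif = tmp_path / "toy.pdb", tmp_path / "toy.cif"
        write_structure(model, pdb)
        write_structure(model, cif)
        a, b = read_structure(pdb), read_structure(cif)
        assert [(x.chain_id, x.atom_name, x.element) for x in a.atoms] == \
               [(x.chain_id, x.atom_name, x.element) for x in b.atoms]
        np.testing.assert_allclose(a.coords(), b.coords(), atol=1e-3)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(ALTLOC_PDB)
        model = read_structure(path)
        ca = [a for a in model.atoms if a.atom_name == "CA"]
        assert len(ca) == 1
        assert ca[0].occupancy == pytest.approx(0.60)
        assert ca[0].xyz[0] == pytest.approx(0.0)

    def test_unparsable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not a structure\n")
        with pytest.raises(ValueError):
            read_structure(bad, format="mmCIF")


class TestSasa:
    def test_single_sphere_analytic(self):
        model = gen_toy_complex("single_sphere")
        # default carbon radius 1.70 A + 1.4 A probe
        analytic = 4 * math.pi * (1.70 + 1.4) ** 2
        assert compute_sasa(model).sum() == pytest.approx(analytic, rel=5e-3)

    def test_single_sphere_custom_radius(self):
        model = gen_toy_complex("single_sphere")
        area = compute_sasa(model, radii={"C": 1.9}).sum()
        assert area == pytest.approx(4 * math.pi * (1.9 + 1.4) ** 2, rel=5e-3)
        assert area == pytest.approx(136.85, rel=5e-3)

    def test_distant_atoms_are_additive(self):
        model = gen_toy_complex("hydrophobic_pair")  # only 4 A apart -> overlap
        far = StructureModel(atoms=(
            model.atoms[0],
            type(model.atoms[0])(**{**model.atoms[1].__dict__,
                                    "xyz": (100.0, 0.0, 0.0)}),
        ))
        analytic = 2 * 4 * math.pi * (1.70 + 1.4) ** 2
        assert compute_sasa(far).sum() == pytest.approx(analytic, rel=5e-3)

    def test_overlapping_spheres_match_monte_carlo_oracle(self):
        model = gen_toy_complex("hydrophobic_pair")
        deterministic = compute_sasa(model).sum()
        oracle = mc_sasa_oracle(model.coords(), [1.70, 1.70])
        assert deterministic == pytest.approx(oracle, rel=0.02)

    def test_rotation_translation_invariance(self):
        model = gen_toy_complex("touching_dimer")
        base = compute_sasa(model).sum()
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0],
                        [0, 0, 1.0]])
        moved = StructureModel(atoms=tuple(
            type(a)(**{**a.__dict__,
                       "xyz": tuple(rot @ np.array(a.xyz) + [5.0, -3.0, 2.0])})
            for a in model.atoms))
        assert compute_sasa(moved).sum() == pytest.approx(base, rel=5e-3)

    def test_point_density_convergence(self):
        model = gen_toy_complex("touching_dimer")
        a960 = compute_sasa(model, n_points=960).sum()
        a3840 = compute_sasa(model, n_points=3840).sum()
        assert abs(a960 - a3840) / a3840 < 0.01

    def test_deterministic(self):
        model = gen_toy_complex("touching_dimer")
        np.testing.assert_array_equal(compute_sasa(model), compute_sasa(model))


class TestBsa:
    def test_separated_chains_bury_nothing(self):
        report = buried_surface_area(gen_toy_complex("far_dimer"), ["A"], ["B"])
        assert report.bsa_peptide == 0.0
        assert report.bsa_receptor == 0.0
        assert report.interface_area == 0.0

    def test_touching_dimer_matches_difference_oracle(self):
        model = gen_toy_complex("touching_dimer")
        report = buried_surface_area(model, ["A"], ["B"])
        assert report.bsa_peptide > 0
        # identity: bsa_A + bsa_B = SASA(A) + SASA(B) - SASA(AB)
        a, b = model.select(chains={"A"}), model.select(chains={"B"})
        lhs = report.bsa_peptide + report.bsa_receptor
        rhs = (compute_sasa(a).sum() + compute_sasa(b).sum()
               - compute_sasa(model).sum())
        assert lhs == pytest.approx(rhs, rel=1e-12)
        assert report.interface_area == pytest.approx(lhs / 2, rel=1e-12)

    def test_per_atom_burial_matches_direct_recomputation(self):
        model = gen_toy_complex("touching_dimer")
        a = model.select(chains={"A"})
        sasa_alone = compute_sasa(a)
        sasa_complex = compute_sasa(model)[: len(a)]
        report = buried_surface_area(model, ["A"], ["B"])
        assert report.bsa_peptide == pytest.approx(
            float(np.sum(sasa_alone - sasa_complex)), rel=1e-12)

    def test_empty_or_overlapping_selection_raises(self):
        model = gen_toy_complex("touching_dimer")
        with pytest.raises(ValueError):
            buried_surface_area(model, ["A"], ["Z"])
        with pytest.raises(ValueError):
            buried_surface_area(model, ["A"], ["A"])


class TestDistancesAndContacts:
    def test_distance_example_and_symmetry(self):
        model = StructureModel(atoms=(
            type(gen_toy_complex("single_sphere").atoms[0])(
                chain_id="A", residue_name="PTR", residue_number=1,
                atom_name="CA", element="C", xyz=(0.0, 0.0, 0.0)),
            type(gen_toy_complex("single_sphere").atoms[0])(
                chain_id="B", residue_name="PTR", residue_number=1,
                atom_name="CA", element="C", xyz=(0.0, 0.0, 23.0)),
        ))
        d_ab = residue_distance(model, ("A", 1), ("B", 1))
        assert d_ab == pytest.approx(23.0)
        assert residue_distance(model, ("B", 1), ("A", 1)) == d_ab
        with pytest.raises(ValueError, match="CB"):
            residue_distance(model, ("A", 1), ("B", 1), atom_name="CB")

    def test_linear_hbond_detected(self):
        contacts = list_contacts(gen_toy_complex("hbond_pair"), ["A"], ["B"])
        hb = [c for c in contacts if c.kind == "hbond"]
        assert len(hb) == 1
        assert hb[0].distance == pytest.approx(2.9)
        assert hb[0].angle_deg == pytest.approx(180.0)

    def test_hydrophobic_contact_detected(self):
        contacts = list_contacts(gen_toy_complex("hydrophobic_pair"), ["A"], ["B"])
        assert [c.kind for c in contacts] == ["hydrophobic"]
        assert contacts[0].distance == pytest.approx(4.0)
        # lone carbons have no covalent polar neighbour -> apolar, flagged
        assert contacts[0].angle_deg is None

    def test_distant_pair_has_no_contacts(self):
        model = gen_toy_complex("hydrophobic_pair")
        moved = StructureModel(atoms=(
            model.atoms[0],
            type(model.atoms[0])(**{**model.atoms[1].__dict__,
                                    "xyz": (6.0, 0.0, 0.0)}),
        ))
        assert list_contacts(moved, ["A"], ["B"]) == []

    def test_symmetric_under_selection_swap(self):
        model = gen_toy_complex("hbond_pair")
        ab = list_contacts(model, ["A"], ["B"])
        ba = list_contacts(model, ["B"], ["A"])
        assert [(c.kind, round(c.distance, 6)) for c in ab] == \
               [(c.kind, round(c.distance, 6)) for c in ba]
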