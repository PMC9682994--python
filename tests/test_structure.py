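"""Structure reading, bond perception and molecule clean-up."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cagetda.structure import (
    FormatError,
    MolecularStructure,
    PointCloud,
    contains_cycle,
    flag_missing_hydrogens,
    heaviest_component,
    infer_bonds,
    read_structure,
    to_point_cloud,
)

WATER_XYZ = """3
water
O 0.000 0.000 0.117
H 0.000 0.757 -0.470
H 0.000 -0.757 -0.470
"""

CIF = """data_test
_cell_length_a 10.0
_cell_length_b 10.0
_cell_length_c 10.0
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 C 0.10 0.10 0.10
C2 C 0.25 0.10 0.10
O1 O 0.40 0.40 0.40
H1 H 0.45 0.40 0.40
"""


def _mol(elements, coords, bonds=None):
    return MolecularStructure("m", list(elements), np.array(coords, float), bonds=bonds)


class TestReaders:
    def test_xyz_water(self, tmp_path):
        p = tmp_path / "water.xyz"
        p.write_text(WATER_XYZ)
        s = read_structure(p)
        assert s.n_atoms == 3
        assert s.coordinate_mode == "cartesian"
        assert s.elements == ["O", "H", "H"]

    def test_cif_fractional(self, tmp_path):
        p = tmp_path / "test.cif"
        p.write_text(CIF)
        s = read_structure(p)
        assert s.n_atoms == 4
        assert s.coordinate_mode == "fractional"
        assert s.cell == (10.0, 10.0, 10.0, 90.0, 90.0, 90.0)
        assert s.elements == ["C", "C", "O", "H"]

    def test_xyz_count_mismatch_is_format_error(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("5\nbad\nC 0 0 0\nC 1 0 0\n")
        with pytest.raises(FormatError):
            read_structure(p)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="unknown element"):
            _mol(["Qq"], [[0, 0, 0]])


class TestInferBonds:
    def test_carbon_pair_within_cutoff_bonded(self):
        s = infer_bonds(_mol("CC", [[0, 0, 0], [1.5, 0, 0]]))
        assert s.bonds == {(0, 1)}

    def test_carbon_pair_beyond_cutoff_not_bonded(self):
        s = infer_bonds(_mol("CC", [[0, 0, 0], [3.0, 0, 0]]))
        assert s.bonds == set()

    def test_h2_bond_from_covalent_radii(self):
        # r_cov(H) = 0.31: 0.74 <= 0.31 + 0.31 + 0.4
        s = infer_bonds(_mol("HH", [[0, 0, 0], [0.74, 0, 0]]))
        assert s.bonds == {(0, 1)}

    def test_fractional_distances_use_cell(self):
        s = MolecularStructure(
            "f", ["C", "C"], np.array([[0.0, 0, 0], [0.15, 0, 0]]),
            coordinate_mode="fractional", cell=(10, 10, 10, 90, 90, 90),
        )
        assert infer_bonds(s).bonds == {(0, 1)}  # 1.5 Å apart in Cartesian

    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        coords = rng.random((n, 3)) * 3
        s = infer_bonds(_mol("C" * n, coords))
        perm = rng.permutation(n)
        s2 = infer_bonds(_mol("C" * n, coords[perm]))
        mapped = {tuple(sorted((int(np.where(perm == i)[0][0]),
                                int(np.where(perm == j)[0][0])))) for i, j in s.bonds}
        assert mapped == set(s2.bonds)


class TestHeaviestComponent:
    def test_cage_beats_waters(self):
        # a 4-C ring plus a lone O far away
        coords = [[0, 0, 0], [1.5, 0, 0], [1.5, 1.5, 0], [0, 1.5, 0], [20, 0, 0]]
        s = infer_bonds(_mol("CCCCO", coords))
        out = heaviest_component(s)
        assert out.elements == ["C", "C", "C", "C"]
        assert out.n_atoms == 4

    def test_single_molecule_unchanged(self):
        s = infer_bonds(_mol("CC", [[0, 0, 0], [1.5, 0, 0]]))
        out = heaviest_component(s)
        assert out.elements == s.elements
        assert np.allclose(out.coordinates, s.coordinates)

    def test_identical_twin_tie_break_takes_lowest_index(self):
        coords = [[0, 0, 0], [1.5, 0, 0], [50, 0, 0], [51.5, 0, 0]]
        out = heaviest_component(infer_bonds(_mol("CCCC", coords)))
        assert np.allclose(out.coordinates, [[0, 0, 0], [1.5, 0, 0]])

    def test_idempotent(self):
        coords = [[0, 0, 0], [1.5, 0, 0], [50, 0, 0]]
        once = heaviest_component(infer_bonds(_mol("CCO", coords)))
        twice = heaviest_component(once)
        assert once.elements == twice.elements
        assert np.allclose(once.coordinates, twice.coordinates)


class TestContainsCycle:
    def test_ring_molecule(self):
        bonds = {(i, (i + 1) % 6) for i in range(6)}
        s = _mol("C" * 6, np.random.default_rng(0).random((6, 3)),
                 bonds={tuple(sorted(b)) for b in bonds})
        assert contains_cycle(s)

    def test_linear_chain_and_single_atom(self):
        chain = _mol("C" * 4, np.zeros((4, 3)) + np.arange(4)[:, None],
                     bonds={(0, 1), (1, 2), (2, 3)})
        assert not contains_cycle(chain)
        atom = _mol("C", [[0, 0, 0]], bonds=set())
        assert not contains_cycle(atom)

    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_dfs_backedge_oracle(self, seed):
        import networkx as nx

        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        g = nx.gnp_random_graph(n, float(rng.uniform(0, 0.4)), seed=int(seed % 2**31))
        s = _mol("C" * n, rng.random((n, 3)),
                 bonds={tuple(sorted(e)) for e in g.edges})
        assert contains_cycle(s) == (len(nx.cycle_basis(g)) > 0)


class TestMissingHydrogenFlag:
    def test_methane_missing_one_h(self):
        coords = [[0, 0, 0], [1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0]]
        s = infer_bonds(_mol("CHHH", coords))
        assert flag_missing_hydrogens(s) == [(0, 1)]

    def test_complete_water_clean(self):
        s = infer_bonds(_mol("OHH", [[0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]]))
        assert flag_missing_hydrogens(s) == []

    def test_benzene_carbons_flagged_as_known_false_positive(self):
        theta = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        coords = 1.39 * np.c_[np.cos(theta), np.sin(theta), np.zeros(6)]
        s = infer_bonds(_mol("C" * 6, coords))
        assert flag_missing_hydrogens(s) == [(i, 2) for i in range(6)]


class TestToPointCloud:
    def test_as_stored_is_identity_for_fractional(self):
        s = MolecularStructure("f", ["C", "C"], np.array([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]]),
                               coordinate_mode="fractional", cell=(10, 10, 10, 90, 90, 90))
        cloud = to_point_cloud(s, "as_stored")
        assert np.array_equal(cloud.points, s.coordinates)

    def test_normalized_diagonal_is_one(self):
        s = _mol("CC", [[0, 0, 0], [10 / 3**0.5] * 3])
        cloud = to_point_cloud(s, "normalized_cartesian")
        extent = cloud.points.max(axis=0) - cloud.points.min(axis=0)
        assert np.isclose(np.linalg.norm(extent), 1.0)

    def test_single_atom_degenerate(self):
        cloud = to_point_cloud(_mol("C", [[3, 3, 3]]), "normalized_cartesian")
        assert np.allclose(cloud.points, 0)
        assert "degenerate" in cloud.scale_note

    def test_degenerate_cell_rejected(self):
        # alpha = beta = 45, gamma = 90 puts all three cell vectors in a plane
        s = MolecularStructure("f", ["C"], np.array([[0.1, 0.1, 0.1]]),
                               coordinate_mode="fractional", cell=(10, 10, 10, 45, 45, 90))
        with pytest.raises(ValueError):
            to_point_cloud(s, "as_stored")
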