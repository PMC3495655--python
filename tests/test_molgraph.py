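"""Molecular-graph model, readers and permutation utilities."""

import pytest
from hypothesis import given, settings, strategies as st

from unismiles import (
    ParseError,
    STANDARD_OPTIONS,
    perceive_aromaticity,
    permute_atoms,
    read_molfile,
    read_smiles,
    to_inchi,
)

ETHANOL_MOLBLOCK = """\
ethanol
  test

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0000    0.5000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
  2  3  1  0  0  0  0
M  END
"""

METHANE_MOLBLOCK = """\
methane
  test

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
"""

# (R)-bromochlorofluoromethane drawn 2D with a wedge to F
WEDGE_MOLBLOCK = """\
bcfm
  test

  4  3  0  0  1  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8660    0.5000    0.0000 Br  0  0  0  0  0  0  0  0  0  0  0  0
    0.8660    0.5000    0.0000 Cl  0  0  0  0  0  0  0  0  0  0  0  0
    0.0000   -1.0000    0.0000 F   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
  1  3  1  0  0  0  0
  1  4  1  1  0  0  0
M  END
"""


class TestReadSmiles:
    def test_atom_order_follows_token_order(self):
        g = read_smiles("ClCC(=O)Br")
        assert [a.element for a in g.atoms] == ["Cl", "C", "C", "O", "Br"]
        double = [b for b in g.bonds if b.order == 2]
        assert len(double) == 1 and {double[0].a, double[0].b} == {2, 3}

    def test_explicit_hydrogens_are_kept(self):
        g = read_smiles("C([2H])O")
        assert [(a.element, a.isotope) for a in g.atoms] == [
            ("C", 0),
            ("H", 2),
            ("O", 0),
        ]
        assert g.atoms[1].is_explicit_h

    def test_dihydrogen(self):
        g = read_smiles("[H][H]")
        assert [a.element for a in g.atoms] == ["H", "H"]
        assert len(g.bonds) == 1

    @pytest.mark.parametrize("bad", ["C1CC", "C(", "[Xx]", "C=1CC=2"])
    def test_invalid_smiles_raises(self, bad):
        with pytest.raises(ParseError):
            read_smiles(bad)

    def test_implicit_valence_filling(self):
        g = read_smiles("C")
        assert g.atoms[0].implicit_h == 4


class TestReadMolfile:
    def test_ethanol_block(self):
        g = read_molfile(ETHANOL_MOLBLOCK)
        assert [a.element for a in g.atoms] == ["C", "C", "O"]
        assert len(g.bonds) == 2 and not g.tet_stereo

    def test_single_atom_methane(self):
        g = read_molfile(METHANE_MOLBLOCK)
        assert g.n_atoms == 1 and g.atoms[0].implicit_h == 4

    def test_wedge_gives_tetrahedral_stereo(self):
        g = read_molfile(WEDGE_MOLBLOCK)
        assert len(g.tet_stereo) == 1
        # same InChI stereo layer as the toolkit's own perception of the
        # matching SMILES
        inchi_block = to_inchi(g, STANDARD_OPTIONS).inchi
        assert "/t" in inchi_block
        smi_variants = {
            to_inchi(read_smiles(s), STANDARD_OPTIONS).inchi
            for s in ("F[C@H](Cl)Br", "F[C@@H](Cl)Br")
        }
        assert inchi_block in smi_variants

    def test_malformed_block_raises(self):
        with pytest.raises(ParseError):
            read_molfile("not a mol block\n")


class TestPermuteAtoms:
    def test_single_atom_identity(self):
        g = read_smiles("C")
        assert permute_atoms(g, 123).atoms == g.atoms

    def test_same_seed_same_permutation(self):
        g = read_smiles("OCC(=O)N")
        a = permute_atoms(g, 5)
        b = permute_atoms(g, 5)
        assert [x.element for x in a.atoms] == [x.element for x in b.atoms]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10**6))
    def test_inchi_invariant_under_permutation(self, seed):
        for smi in ["OCC", "F[C@H](Cl)Br", "F/C=C/F", "c1ccncc1"]:
            g = read_smiles(smi)
            ref = to_inchi(g, STANDARD_OPTIONS).inchi
            assert to_inchi(permute_atoms(g, seed), STANDARD_OPTIONS).inchi == ref

    def test_invariant_multiset(self):
        g = read_smiles("CC(=O)[O-].[Na+]")
        gp = permute_atoms(g, 9)
        key = lambda gg: sorted(
            (a.element, a.charge, a.isotope, len(gg.neighbors(a.index)))
            for a in gg.atoms
        )
        assert key(g) == key(gp)

    def test_components_stable_up_to_relabeling(self):
        g = read_smiles("C.CC.CCC")
        sizes = sorted(len(c) for c in g.components)
        assert sorted(len(c) for c in permute_atoms(g, 3).components) == sizes


class TestAromaticity:
    def test_kekule_benzene_perceived(self):
        g = read_smiles("C1=CC=CC=C1")
        assert all(a.aromatic for a in g.atoms)
        assert all(b.aromatic for b in g.bonds)

    def test_cyclohexane_not_aromatic(self):
        g = read_smiles("C1CCCCC1")
        assert not any(a.aromatic for a in g.atoms)

    def test_vinyl_side_chain_not_aromatic(self):
        g = read_smiles("c1cc(/C=C/F)cc(c1)[N+](=O)[O-]")
        ring = [a for a in g.atoms if a.aromatic]
        assert len(ring) == 6
        assert not g.atoms[3].aromatic  # vinyl carbon

    def test_perceive_is_idempotent(self):
        g = perceive_aromaticity(read_smiles("c1ccc2ccccc2c1"))
        g2 = perceive_aromaticity(g)
        assert [a.aromatic for a in g.atoms] == [a.aromatic for a in g2.atoms]
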