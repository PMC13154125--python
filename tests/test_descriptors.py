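"""Descriptor blocks: exact shape values, library cross-checks, invariances."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors3D, rdMolDescriptors
from scipy.stats import special_ortho_group

from xtalgroup.descriptors import (
    ALL_FEATURE_NAMES,
    FeatureTable,
    assemble_features,
    chemical_features,
    general_features,
    select_features,
    shape_descriptors,
)

import pandas as pd


def embedded(smiles: str, seed: int = 1):
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, params) == 0
    conf = mol.GetConformer()
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    return mol, [a.GetSymbol() for a in mol.GetAtoms()], coords


class TestGeneralFeatures:
    def test_benzene_counts(self):
        mol = Chem.MolFromSmiles("c1ccccc1")
        feats = general_features(mol)
        assert feats["n_atoms"] == 12
        assert feats["n_rings"] == 1
        assert feats["n_aromatic_rings"] == 1

    def test_methane_counts(self):
        feats = general_features(Chem.MolFromSmiles("C"))
        assert feats["n_atoms"] == 5
        assert feats["n_rings"] == 0

    def test_water_molecular_weight(self):
        assert general_features(Chem.MolFromSmiles("O"))["mol_weight"] == pytest.approx(
            18.015, abs=0.01
        )


class TestShapeDescriptors:
    def test_tetrahedron_is_spherical_top(self):
        coords = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
        d = shape_descriptors(["C"] * 4, coords)
        assert d.npr1 == pytest.approx(1.0, abs=1e-12)
        assert d.npr2 == pytest.approx(1.0, abs=1e-12)
        assert d.asphericity == pytest.approx(0.0, abs=1e-12)
        assert d.eccentricity == pytest.approx(0.0, abs=1e-9)

    def test_collinear_rod_limits(self):
        coords = np.array([[-1.0, 0, 0], [0, 0, 0], [1.0, 0, 0]])
        d = shape_descriptors(["C"] * 3, coords)
        assert d.npr1 == pytest.approx(0.0, abs=1e-12)
        assert d.npr2 == pytest.approx(1.0, abs=1e-12)
        assert d.eccentricity == pytest.approx(1.0, abs=1e-12)
        # gyration convention: a perfect rod has maximal asphericity
        assert d.asphericity == pytest.approx(1.0, abs=1e-12)

    def test_regular_hexagon_disc(self):
        # perpendicular-axis theorem: I3 = I1 + I2 with I1 = I2, so NPR = 0.5
        angles = np.pi * np.arange(6) / 3.0
        coords = np.stack([np.cos(angles), np.sin(angles), np.zeros(6)], axis=1)
        d = shape_descriptors(["C"] * 6, coords)
        assert d.npr1 == pytest.approx(0.5, abs=1e-12)
        assert d.npr2 == pytest.approx(0.5, abs=1e-12)
        assert d.planarity == pytest.approx(0.0, abs=1e-12)

    def test_bounds_on_random_point_clouds(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(4, 20))
            coords = rng.normal(size=(n, 3)) * rng.uniform(0.2, 3.0, size=3)
            d = shape_descriptors(["C"] * n, coords)
            assert 0.0 <= d.npr1 <= d.npr2 <= 1.0 + 1e-12
            assert d.npr1 + d.npr2 >= 1.0 - 1e-12
            assert 0.0 <= d.asphericity <= 1.0 + 1e-12
            assert 0.0 <= d.eccentricity <= 1.0 + 1e-12
            assert d.planarity >= 0.0

    def test_matches_reference_descriptor_library(self):
        """Independent cross-check against RDKit's 3D descriptor implementations."""
        for smiles in ("CCO", "c1ccccc1C(=O)O", "CC(C)CC1CCC(O)CC1"):
            mol, elements, coords = embedded(smiles)
            d = shape_descriptors(elements, coords)
            assert d.npr1 == pytest.approx(Descriptors3D.NPR1(mol), abs=1e-6)
            assert d.npr2 == pytest.approx(Descriptors3D.NPR2(mol), abs=1e-6)
            assert d.asphericity == pytest.approx(Descriptors3D.Asphericity(mol), abs=1e-6)
            assert d.eccentricity == pytest.approx(Descriptors3D.Eccentricity(mol), abs=1e-6)
            assert d.planarity == pytest.approx(rdMolDescriptors.CalcPBF(mol), abs=1e-6)

    def test_too_few_atoms(self):
        with pytest.raises(ValueError):
            shape_descriptors(["C", "C"], np.array([[0.0, 0, 0], [1.0, 0, 0]]))


class TestChemicalFeatures:
    def test_benzene_all_zero(self):
        feats = chemical_features("c1ccccc1")
        assert all(v == 0 for k, v in feats.items() if k.startswith("fg_"))
        assert feats["tpsa"] == 0.0

    def test_ethanol(self):
        feats = chemical_features("CCO")
        assert feats["fg_alcohol"] == 1
        assert feats["tpsa"] == pytest.approx(20.23, abs=0.01)
        assert all(
            v == 0 for k, v in feats.items() if k.startswith("fg_") and k != "fg_alcohol"
        )

    def test_aspirin_disambiguation(self):
        feats = chemical_features("CC(=O)Oc1ccccc1C(=O)O")
        assert feats["fg_carboxylic_acid"] == 1
        assert feats["fg_ester"] == 1
        assert feats["fg_ether"] == 0
        assert feats["fg_ketone"] == 0

    @pytest.mark.parametrize(
        "smiles,group,count",
        [
            ("CCO", "alcohol", 1),
            ("CC(=O)NC", "amide", 1),
            ("CC=NC", "imine", 1),
            ("c1ccccc1[N+](=O)[O-]", "nitro", 1),
            ("CC#N", "nitrile", 1),
            ("CCN", "amine", 1),
            ("CCOCC", "ether", 1),
            ("CC=O", "aldehyde", 1),
            ("CCCl", "halide", 1),
            ("FC(F)(F)c1ccccc1", "halide", 3),
            ("CC(=O)CC", "ketone", 1),
            ("CC(=O)O", "carboxylic_acid", 1),
            ("CC(=O)OC(C)=O", "anhydride", 1),
            ("CC(=O)OC", "ester", 1),
            ("CCS", "thiol", 1),
            ("CC(=S)N", "thiocarbonyl", 1),
            ("CSC", "thioether", 1),
            ("CS(C)(=O)=O", "sulfone", 1),
            ("OP(=O)(O)OC", "phosphoric_acid", 1),
        ],
    )
    def test_single_group_molecules(self, smiles, group, count):
        assert chemical_features(smiles)[f"fg_{group}"] == count

    def test_anhydride_not_double_counted_as_ester(self):
        feats = chemical_features("CC(=O)OC(C)=O")
        assert feats["fg_ester"] == 0
        assert feats["fg_ether"] == 0

    def test_amide_nitrogen_not_an_amine(self):
        assert chemical_features("CC(=O)NC")["fg_amine"] == 0

    def test_counts_invariant_to_atom_ordering(self):
        rng = np.random.default_rng(4)
        for smiles in ("CC(=O)Oc1ccccc1C(=O)O", "NCC(O)c1ccc(S)cc1"):
            mol = Chem.MolFromSmiles(smiles)
            base = chemical_features(smiles)
            for _ in range(3):
                order = list(rng.permutation(mol.GetNumAtoms()))
                shuffled = Chem.MolToSmiles(
                    Chem.RenumberAtoms(mol, [int(i) for i in order]), canonical=False
                )
                got = chemical_features(shuffled)
                for k in base:
                    assert got[k] == pytest.approx(base[k], abs=1e-9), k

    def test_unparsable_smiles_raises(self):
        with pytest.raises(ValueError):
            chemical_features("not_a_smiles")


class TestAssembleAndSelect:
    def test_schema_and_row_count(self, small_dataset):
        table = assemble_features(small_dataset[:60])
        assert len(table.frame) == 60
        assert list(table.frame.columns) == list(ALL_FEATURE_NAMES)
        assert set(table.column_class.values()) == {"general", "geometric", "chemical"}

    def test_geometric_block_invariant_to_rigid_motion(self, small_dataset):
        records = small_dataset[:15]
        table = assemble_features(records)
        rng = np.random.default_rng(8)
        rot = special_ortho_group.rvs(3, random_state=rng)
        shift = rng.normal(size=3)
        import dataclasses

        moved = [
            dataclasses.replace(r, coordinates=r.coordinates @ rot.T + shift)
            for r in records
        ]
        table2 = assemble_features(moved)
        geo_cols = [c for c, cl in table.column_class.items() if cl == "geometric"]
        shape_cols = [c for c in geo_cols if not c.startswith(("sym_", "n_sym"))]
        assert np.allclose(
            table.frame[shape_cols].to_numpy(),
            table2.frame[shape_cols].to_numpy(),
            atol=1e-8,
        )
        # symmetry census columns are integer counts: must match exactly
        sym_cols = [c for c in geo_cols if c not in shape_cols]
        assert (table.frame[sym_cols].to_numpy() == table2.frame[sym_cols].to_numpy()).all()

    def test_duplicate_column_dropped(self):
        frame = pd.DataFrame(
            {"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [4.0, 1, 3, 2]}
        )
        table = FeatureTable(frame=frame, column_class={k: "general" for k in frame})
        out = select_features(table, corr_threshold=0.9, var_threshold=1e-8)
        assert out.column_names == ["a", "c"]

    def test_constant_column_dropped(self):
        frame = pd.DataFrame({"a": [1.0, 1, 1, 1], "b": [4.0, 1, 3, 2]})
        table = FeatureTable(frame=frame, column_class={k: "general" for k in frame})
        out = select_features(table)
        assert out.column_names == ["b"]

    def test_independent_columns_all_retained(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.normal(size=(1000, 8)), columns=list("abcdefgh"))
        table = FeatureTable(frame=frame, column_class={k: "general" for k in frame})
        out = select_features(table, corr_threshold=0.9)
        assert out.column_names == list("abcdefgh")

    def test_selection_idempotent_and_transferable(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(200, 3))
        frame = pd.DataFrame(
            {"a": base[:, 0], "dup": base[:, 0] * 2.0, "b": base[:, 1], "c": base[:, 2]}
        )
        table = FeatureTable(frame=frame, column_class={k: "general" for k in frame})
        first = select_features(table)
        second = select_features(first)
        assert second.column_names == first.column_names
        other = FeatureTable(
            frame=frame + 1.0, column_class={k: "general" for k in frame}
        )
        applied = select_features(other, selection=first.selection)
        assert applied.column_names == first.column_names

    def test_all_columns_removed_raises(self):
        frame = pd.DataFrame({"a": [1.0, 1, 1], "b": [2.0, 2, 2]})
        table = FeatureTable(frame=frame, column_class={k: "general" for k in frame})
        with pytest.raises(ValueError):
            select_features(table)
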