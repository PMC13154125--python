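"""Synthetic molecule/space-group datasets with planted, learnable structure.

Real space-group labels come from licensed crystal-structure databases, so
this module generates stand-in datasets with the statistical features the
downstream analysis assumes: a highly uneven space-group marginal, polymorph
families (same molecule, a second distinct label), chiral molecules restricted
to the 65 Sohncke groups, and a planted probabilistic dependence of the label
on molecular descriptors (planarity, hydrogen-bonding group counts, symmetry).

Molecules are assembled from a small curated fragment grammar (aromatic and
aliphatic scaffolds x substituents covering 18 common functional groups),
guaranteeing valence-correct chemistry, and embedded in 3D with seeded ETKDG.
Labels are drawn from

    p(c | molecule) = softmax( log pi_c + (sum_f w_f s_{f,c} z_f) / T )

where ``pi`` is the configured label marginal, ``z_f`` are the standardized
true descriptor values, ``w_f`` the planted weights, ``s_{f,c}`` a fixed
seeded sign pattern giving each class its own direction, and ``T`` the noise
temperature (the marginal is recovered exactly when all weights are zero).
All distributions here are synthetic defaults, not measured data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from ._sohncke import SOHNCKE_GROUPS
from .dataset import (
    PROP_CHIRAL,
    PROP_FAMILY,
    PROP_GEOMETRY_SOURCE,
    PROP_RANK,
    PROP_SMILES,
    PROP_SPACE_GROUP,
    MoleculeRecord,
    records_to_mol,
)

RDLogger.DisableLog("rdApp.*")


class ConfigurationError(ValueError):
    pass


class EmptyDatasetError(ValueError):
    pass


# ---------------------------------------------------------------------------
# fragment grammar

# one- and two-slot scaffold templates ({} = substituent attachment)
SCAFFOLDS_1: tuple[str, ...] = (
    "c1ccc({})cc1",        # benzene
    "c1ccnc({})c1",        # pyridine
    "c1cc({})oc1",         # furan
    "c1cc({})sc1",         # thiophene
    "c1cc({})[nH]c1",      # pyrrole
    "C1CCC({})CC1",        # cyclohexane
    "C1CCC({})C1",         # cyclopentane
    "c1ccc2cc({})ccc2c1",  # naphthalene
    "C1CCN({})CC1",        # piperidine (N-substituted)
    "CC({})C",             # isopropyl core
    "CCC({})CC",           # pentane core
)
SCAFFOLDS_2: tuple[str, ...] = (
    "c1ccc({})c({})c1",    # ortho-disubstituted benzene
    "c1cc({})ccc1{}",      # para-disubstituted benzene
    "c1cc({})nc({})c1",    # disubstituted pyridine
    "C1CCC({})C({})C1",    # 1,2-cyclohexane
    "C({})CC{}",           # 1,3-propane
    "c1c({})cc({})cc1",    # meta-disubstituted benzene
    "C1CC({})CC({})C1",    # 1,3-cyclohexane
    "CC({})CC({})C",       # branched pentane
    "c1cc2ccc({})cc2cc1{}",  # disubstituted naphthalene
)

# substituents, chosen to cover the 18 counted functional groups
SUBSTITUENTS: tuple[str, ...] = (
    "O",                # alcohol / phenol
    "CO",               # hydroxymethyl
    "C(=O)N",           # amide
    "NC(C)=O",          # acetamido
    "C(C)=NC",          # imine
    "[N+](=O)[O-]",     # nitro
    "C#N",              # nitrile
    "N",                # primary amine
    "NC",               # secondary amine
    "N(C)C",            # tertiary amine
    "OC",               # methyl ether
    "OCC",              # ethyl ether
    "C=O",              # aldehyde
    "F",
    "Cl",
    "Br",
    "I",
    "C(C)=O",           # methyl ketone
    "C(=O)O",           # carboxylic acid
    "C(=O)OC(C)=O",     # anhydride
    "C(=O)OC",          # methyl ester
    "OC(C)=O",          # acetoxy ester
    "S",                # thiol
    "C(=S)N",           # thioamide (thiocarbonyl)
    "SC",               # thioether
    "S(C)(=O)=O",       # sulfone
    "OP(=O)(O)O",       # phosphoric acid
    "C",                # methyl
    "CC",               # ethyl
    "C(C)C",            # isopropyl
)
CHIRAL_SUBSTITUENTS: tuple[str, ...] = (
    "[C@@H](C)O",       # chiral sec-alcohol
    "[C@@H](C)N",       # chiral amine
    "[C@@H](C)C(=O)O",  # chiral acid
    "[C@@H](C)OC",      # chiral ether
)

# Synthetic stand-in for the uneven space-group frequencies of organic
# crystals: dominated by P21/c(14), P-1(2), P212121(19), C2/c(15), P21(4).
_MARGINAL_25_RAW: dict[int, float] = {
    14: 0.345, 2: 0.230, 19: 0.075, 15: 0.073, 4: 0.055, 61: 0.036, 33: 0.018,
    9: 0.012, 29: 0.011, 1: 0.010, 5: 0.008, 60: 0.007, 62: 0.006, 7: 0.005,
    13: 0.005, 88: 0.004, 148: 0.004, 56: 0.003, 43: 0.003, 96: 0.003,
    18: 0.002, 76: 0.002, 145: 0.002, 169: 0.002, 78: 0.002,
}
_Z = sum(_MARGINAL_25_RAW.values())
DEFAULT_MARGINAL_25: dict[int, float] = {k: v / _Z for k, v in _MARGINAL_25_RAW.items()}
_TOP10 = dict(sorted(_MARGINAL_25_RAW.items(), key=lambda kv: -kv[1])[:10])
_Z10 = sum(_TOP10.values())
DEFAULT_MARGINAL_10: dict[int, float] = {k: v / _Z10 for k, v in _TOP10.items()}

DEFAULT_PLANTED_WEIGHTS: dict[str, float] = {
    "planarity": 2.0,
    "n_sym_ops": 1.2,
    "fg_alcohol": 1.6,
    "fg_amide": 1.6,
    "fg_carboxylic_acid": 1.4,
    "tpsa": 1.2,
    "npr1": 1.0,
}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_molecules: int
    label_marginal: dict[int, float]
    planted_weights: dict[str, float] = field(default_factory=dict)
    polymorph_rate: float = 0.0
    chiral_fraction: float = 0.0
    noise_temperature: float = 1.0
    seed: int = 0
    library_size: int = 400  # distinct molecules in the fragment library

    def __post_init__(self) -> None:
        if self.n_molecules <= 0:
            raise EmptyDatasetError("n_molecules must be positive")
        probs = np.array(list(self.label_marginal.values()), dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("label_marginal must be nonnegative and sum to 1")
        for sg in self.label_marginal:
            if not 1 <= int(sg) <= 230:
                raise ConfigurationError(f"space group {sg} outside 1-230")
        for name, rate in (
            ("polymorph_rate", self.polymorph_rate),
            ("chiral_fraction", self.chiral_fraction),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.noise_temperature <= 0:
            raise ConfigurationError("noise_temperature must be positive")
        if self.chiral_fraction > 0 and not any(
            sg in SOHNCKE_GROUPS for sg in self.label_marginal
        ):
            raise ConfigurationError(
                "chiral_fraction > 0 requires at least one Sohncke group in the marginal"
            )


def default_config(seed: int = 0, n_molecules: int = 5000) -> GeneratorConfig:
    """Documented default planted-rule conditions: 10 classes, strong signal."""
    return GeneratorConfig(
        n_molecules=n_molecules,
        label_marginal=dict(DEFAULT_MARGINAL_10),
        planted_weights=dict(DEFAULT_PLANTED_WEIGHTS),
        polymorph_rate=0.02,
        chiral_fraction=0.1,
        noise_temperature=0.35,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# molecule assembly


def _embed_smiles(smiles: str) -> tuple[list[str], np.ndarray] | None:
    """Deterministic 3D embedding (ETKDG, seed derived from the SMILES)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = zlib.crc32(smiles.encode()) & 0x7FFFFFFF
    if AllChem.EmbedMolecule(mol, params) != 0:
        return None
    conf = mol.GetConformer()
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    return [a.GetSymbol() for a in mol.GetAtoms()], coords


def _assemble_smiles(rng: np.random.Generator, chiral: bool) -> str | None:
    subs = SUBSTITUENTS
    if chiral:
        first = CHIRAL_SUBSTITUENTS[rng.integers(len(CHIRAL_SUBSTITUENTS))]
    else:
        first = subs[rng.integers(len(subs))]
    if rng.random() < 0.5:
        template = SCAFFOLDS_1[rng.integers(len(SCAFFOLDS_1))]
        smi = template.format(first)
    else:
        template = SCAFFOLDS_2[rng.integers(len(SCAFFOLDS_2))]
        second = subs[rng.integers(len(subs))]
        smi = template.format(first, second)
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def _build_library(
    rng: np.random.Generator, size: int, chiral: bool
) -> list[tuple[str, list[str], np.ndarray]]:
    out: list[tuple[str, list[str], np.ndarray]] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < size and attempts < 50 * size:
        attempts += 1
        smi = _assemble_smiles(rng, chiral)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        emb = _embed_smiles(smi)
        if emb is None:
            continue
        out.append((smi, emb[0], emb[1]))
    if not out:
        raise RuntimeError("fragment grammar produced no embeddable molecules")
    return out


def _planted_feature_matrix(
    library: list[tuple[str, list[str], np.ndarray]], feature_names: list[str]
) -> np.ndarray:
    # local import: descriptors imports dataset, not synthetic_data, so no cycle
    from .descriptors import compute_feature_row

    rows = []
    for smi, elements, coords in library:
        rec = MoleculeRecord(
            record_id="tmp",
            family_id="tmp",
            smiles=smi,
            elements=elements,
            coordinates=coords,
            space_group=1,
        )
        row = compute_feature_row(rec, tolerance=0.05)
        rows.append([row[name] for name in feature_names])
    return np.array(rows, dtype=float)


def generate_dataset(config: GeneratorConfig) -> list[MoleculeRecord]:
    """Generate molecule records with labels from the planted softmax rule.

    Deterministic for a fixed config (including seed). Chiral records receive
    only Sohncke-group labels; polymorph families share a family id and get a
    second, different label drawn from the same softmax with the first label
    excluded.
    """
    rng = np.random.default_rng(config.seed)
    classes = np.array(sorted(config.label_marginal), dtype=int)
    log_pi = np.log(
        np.maximum(np.array([config.label_marginal[c] for c in classes]), 1e-300)
    )
    sohncke_mask = np.array([c in SOHNCKE_GROUPS for c in classes])

    n_chiral_lib = (
        max(4, config.library_size // 5) if config.chiral_fraction > 0 else 0
    )
    achiral_lib = _build_library(rng, config.library_size, chiral=False)
    chiral_lib = _build_library(rng, n_chiral_lib, chiral=True) if n_chiral_lib else []

    feature_names = sorted(config.planted_weights)
    if feature_names:
        full = achiral_lib + chiral_lib
        feats = _planted_feature_matrix(full, feature_names)
        mu = feats.mean(axis=0)
        sd = feats.std(axis=0)
        sd[sd < 1e-12] = 1.0
        z = (feats - mu) / sd
        w = np.array([config.planted_weights[f] for f in feature_names])
        # fixed seeded sign pattern gives each class its own planted direction
        pattern_rng = np.random.default_rng((config.seed * 2654435761 + 17) % (2**31))
        signs = pattern_rng.choice([-1.0, 1.0], size=(len(feature_names), len(classes)))
        scores_by_idx = (z * w) @ signs / config.noise_temperature
        score_lookup = {full[i][0]: scores_by_idx[i] for i in range(len(full))}
    else:
        score_lookup = {}

    def label_probs(smiles: str, chiral: bool, exclude: int | None = None) -> np.ndarray:
        logits = log_pi + score_lookup.get(smiles, 0.0)
        logits = logits - logits.max()
        p = np.exp(logits)
        if chiral:
            p = p * sohncke_mask
        if exclude is not None:
            p = p * (classes != exclude)
        total = p.sum()
        if total <= 0:
            raise ConfigurationError("no admissible space group for this record")
        return p / total

    records: list[MoleculeRecord] = []
    for i in range(config.n_molecules):
        chiral = bool(rng.random() < config.chiral_fraction) and bool(chiral_lib)
        lib = chiral_lib if chiral else achiral_lib
        smi, elements, coords = lib[rng.integers(len(lib))]
        fam = f"fam{i:06d}"
        p = label_probs(smi, chiral)
        sg = int(classes[rng.choice(len(classes), p=p)])
        records.append(
            MoleculeRecord(
                record_id=f"{fam}-1",
                family_id=fam,
                smiles=smi,
                elements=list(elements),
                coordinates=coords.copy(),
                space_group=sg,
                deposition_rank=1,
                chiral=chiral,
            )
        )
        if rng.random() < config.polymorph_rate and len(classes) > 1:
            p2 = label_probs(smi, chiral, exclude=sg)
            if p2.sum() > 0:
                sg2 = int(classes[rng.choice(len(classes), p=p2)])
                records.append(
                    MoleculeRecord(
                        record_id=f"{fam}-2",
                        family_id=fam,
                        smiles=smi,
                        elements=list(elements),
                        coordinates=coords.copy(),
                        space_group=sg2,
                        deposition_rank=2,
                        chiral=chiral,
                    )
                )
    if not records:
        raise EmptyDatasetError("generator produced no records")
    return records


# ---------------------------------------------------------------------------
# fixture geometries


@dataclass
class FixtureGeometry:
    name: str
    elements: list[str]
    coordinates: np.ndarray
    expected_point_group: str
    expected_total_operations: int | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(self.elements) < 2 or not np.all(np.isfinite(self.coordinates)):
            raise ValueError("fixture needs >= 2 atoms with finite coordinates")


def fixture_geometries() -> list[FixtureGeometry]:
    """Exact reference geometries for symmetry/descriptor unit tests."""
    fixtures = []
    fixtures.append(
        FixtureGeometry(
            name="water",
            elements=["O", "H", "H"],
            coordinates=[[0.0, 0.0, 0.1173], [0.0, 0.7572, -0.4692], [0.0, -0.7572, -0.4692]],
            expected_point_group="C2v",
            expected_total_operations=4,
        )
    )
    rc, rh = 1.39, 2.48
    coords, elements = [], []
    for k in range(6):
        a = np.pi * k / 3.0
        coords.append([rc * np.cos(a), rc * np.sin(a), 0.0])
        elements.append("C")
    for k in range(6):
        a = np.pi * k / 3.0
        coords.append([rh * np.cos(a), rh * np.sin(a), 0.0])
        elements.append("H")
    fixtures.append(
        FixtureGeometry(
            name="benzene",
            elements=elements,
            coordinates=coords,
            expected_point_group="D6h",
            expected_total_operations=24,
        )
    )
    d = 1.09 / np.sqrt(3.0)
    fixtures.append(
        FixtureGeometry(
            name="methane",
            elements=["C", "H", "H", "H", "H"],
            coordinates=[
                [0.0, 0.0, 0.0],
                [d, d, d],
                [d, -d, -d],
                [-d, d, -d],
                [-d, -d, d],
            ],
            expected_point_group="Td",
            expected_total_operations=24,
        )
    )
    fixtures.append(
        FixtureGeometry(
            name="carbon_dioxide",
            elements=["O", "C", "O"],
            coordinates=[[0.0, 0.0, -1.16], [0.0, 0.0, 0.0], [0.0, 0.0, 1.16]],
            expected_point_group="Dinfh",
        )
    )
    fixtures.append(
        FixtureGeometry(
            name="asymmetric",
            elements=["C", "N", "O", "S"],
            coordinates=[
                [0.0, 0.0, 0.0],
                [1.45, 0.1, -0.2],
                [0.3, 1.37, 0.5],
                [-0.8, -0.6, 1.55],
            ],
            expected_point_group="C1",
            expected_total_operations=1,
        )
    )
    return fixtures


# ---------------------------------------------------------------------------
# SDF output


def write_sdf(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write records as a V2000 SDF with label/family/chirality properties.

    Round-trips losslessly through ``dataset.read_sdf`` (coordinates to the
    4 decimal places of the SDF format).
    """
    if not records:
        raise ValueError("no records to write")
    for rec in records:
        if not 1 <= rec.space_group <= 230:
            raise ValueError(f"space group {rec.space_group} outside 1-230")
    writer = Chem.SDWriter(str(path))
    try:
        for rec in records:
            mol = records_to_mol(rec)
            mol.SetProp("_Name", rec.record_id)
            mol.SetProp(PROP_SPACE_GROUP, str(rec.space_group))
            mol.SetProp(PROP_FAMILY, rec.family_id)
            mol.SetProp(PROP_CHIRAL, "1" if rec.chiral else "0")
            mol.SetProp(PROP_RANK, str(rec.deposition_rank))
            mol.SetProp(PROP_GEOMETRY_SOURCE, rec.geometry_source)
            mol.SetProp(PROP_SMILES, rec.smiles)
            writer.write(mol)
    finally:
        writer.close()
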