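"""Dataset curation: record container, SDF I/O, polymorph handling, balancing, splits.

The curation pipeline mirrors how crystal-structure datasets are prepared for
space-group prediction: collapse polymorph families to a single deposition (or
to one record per distinct space group), optionally balance the very uneven
space-group label distribution by subsampling the ``k`` most frequent groups,
and produce train/validation/test splits (stratified splits keep the label
histogram even across the three parts).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from ._sohncke import is_sohncke

logger = logging.getLogger(__name__)

# SDF property tags used for round-tripping records.
PROP_SPACE_GROUP = "space_group"
PROP_FAMILY = "family_id"
PROP_CHIRAL = "chiral"
PROP_RANK = "deposition_rank"
PROP_GEOMETRY_SOURCE = "geometry_source"
PROP_SMILES = "smiles"


@dataclass
class MoleculeRecord:
    """One molecule/conformer with its space-group label.

    ``family_id`` groups polymorphs of the same molecule; ``deposition_rank``
    orders records within a family (rank 1 = first deposited structure).
    ``geometry_source`` records whether the conformer is a relaxed gas-phase
    geometry or taken from a crystal structure.
    """

    record_id: str
    family_id: str
    smiles: str
    elements: list[str]
    coordinates: np.ndarray  # (n_atoms, 3) Cartesian angstroms
    space_group: int
    deposition_rank: int = 1
    chiral: bool = False
    geometry_source: str = "optimized"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not (1 <= self.space_group <= 230):
            raise ValueError(
                f"space group {self.space_group} outside 1-230 for {self.record_id}"
            )
        if self.coordinates.shape != (len(self.elements), 3):
            raise ValueError(f"coordinate/element mismatch for {self.record_id}")
        if len(self.elements) < 2:
            raise ValueError(f"fewer than 2 atoms in {self.record_id}")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"non-finite coordinates in {self.record_id}")
        if self.geometry_source not in ("optimized", "crystal"):
            raise ValueError(f"bad geometry_source {self.geometry_source!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class SpaceGroupLabel:
    number: int
    sohncke: bool = field(init=False)

    def __post_init__(self) -> None:
        if not (1 <= self.number <= 230):
            raise ValueError(f"space group {self.number} outside 1-230")
        self.sohncke = is_sohncke(self.number)


@dataclass
class DatasetSplit:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    fractions: tuple[float, float, float]
    seed: int
    stratified: bool

    def __post_init__(self) -> None:
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split parts are not disjoint")


def records_to_mol(record: MoleculeRecord) -> Chem.Mol:
    """Rebuild an RDKit molecule (with conformer) from a record's SMILES + coords."""
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES for {record.record_id}: {record.smiles}")
    mol = Chem.AddHs(mol)
    if mol.GetNumAtoms() != record.n_atoms:
        raise ValueError(
            f"SMILES atom count {mol.GetNumAtoms()} != record atom count "
            f"{record.n_atoms} for {record.record_id}"
        )
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(record.coordinates):
        conf.SetAtomPosition(i, [float(v) for v in xyz])
    mol.AddConformer(conf, assignId=True)
    return mol


def read_sdf(path: str | Path) -> list[MoleculeRecord]:
    """Read molecule records from an SDF file.

    Entries missing the space-group property (or otherwise malformed) are
    skipped with a logged warning; a file yielding zero valid records raises.
    """
    path = Path(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    records: list[MoleculeRecord] = []
    n_skipped = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            n_skipped += 1
            logger.warning("skipping malformed SDF entry %d in %s", i, path)
            continue
        if not mol.HasProp(PROP_SPACE_GROUP):
            n_skipped += 1
            logger.warning("skipping entry %d in %s: no space-group property", i, path)
            continue
        try:
            sg = int(mol.GetProp(PROP_SPACE_GROUP))
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"rec{i}"
            conf = mol.GetConformer()
            coords = np.array(
                [list(conf.GetAtomPosition(j)) for j in range(mol.GetNumAtoms())]
            )
            rec = MoleculeRecord(
                record_id=name,
                family_id=mol.GetProp(PROP_FAMILY) if mol.HasProp(PROP_FAMILY) else name,
                smiles=mol.GetProp(PROP_SMILES)
                if mol.HasProp(PROP_SMILES)
                else Chem.MolToSmiles(Chem.RemoveHs(mol)),
                elements=[a.GetSymbol() for a in mol.GetAtoms()],
                coordinates=coords,
                space_group=sg,
                deposition_rank=int(mol.GetProp(PROP_RANK)) if mol.HasProp(PROP_RANK) else 1,
                chiral=mol.GetProp(PROP_CHIRAL) == "1" if mol.HasProp(PROP_CHIRAL) else False,
                geometry_source=mol.GetProp(PROP_GEOMETRY_SOURCE)
                if mol.HasProp(PROP_GEOMETRY_SOURCE)
                else "optimized",
            )
        except (ValueError, KeyError) as exc:
            n_skipped += 1
            logger.warning("skipping entry %d in %s: %s", i, path, exc)
            continue
        records.append(rec)
    if n_skipped:
        logger.info("read_sdf: skipped %d of %d entries in %s", n_skipped, i + 1, path)
    if not records:
        raise ValueError(f"no valid records in {path}")
    return records


def first_polymorph_only(records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Keep one record per family: the lowest deposition rank (first deposited)."""
    best: dict[str, MoleculeRecord] = {}
    for rec in records:
        cur = best.get(rec.family_id)
        if cur is None or rec.deposition_rank < cur.deposition_rank:
            best[rec.family_id] = rec
    # preserve input order of the retained records
    kept = set(id(r) for r in best.values())
    return [r for r in records if id(r) in kept]


def unique_space_group_polymorphs(
    records: Sequence[MoleculeRecord],
) -> list[MoleculeRecord]:
    """Per family, keep one record per distinct space group (lowest rank wins)."""
    best: dict[tuple[str, int], MoleculeRecord] = {}
    for rec in records:
        key = (rec.family_id, rec.space_group)
        cur = best.get(key)
        if cur is None or rec.deposition_rank < cur.deposition_rank:
            best[key] = rec
    kept = set(id(r) for r in best.values())
    return [r for r in records if id(r) in kept]


def balanced_subset(
    records: Sequence[MoleculeRecord], k_groups: int, seed: int
) -> list[MoleculeRecord]:
    """Balanced subsample over the ``k_groups`` most frequent space groups.

    Frequency ties are broken by the lower space-group number. The per-label
    quota is the count of the least frequent retained label, so the output
    label histogram is exactly uniform with ``k_groups * m`` records.
    """
    counts = Counter(r.space_group for r in records)
    if k_groups > len(counts):
        raise ValueError(
            f"k_groups={k_groups} exceeds the {len(counts)} distinct labels present"
        )
    order = sorted(counts, key=lambda sg: (-counts[sg], sg))
    keep = order[:k_groups]
    m = min(counts[sg] for sg in keep)
    rng = np.random.default_rng(seed)
    by_label: dict[int, list[MoleculeRecord]] = defaultdict(list)
    for rec in records:
        if rec.space_group in keep:
            by_label[rec.space_group].append(rec)
    out: list[MoleculeRecord] = []
    for sg in keep:
        pool = by_label[sg]
        idx = rng.choice(len(pool), size=m, replace=False)
        out.extend(pool[j] for j in sorted(idx))
    return out


def split(
    records: Sequence[MoleculeRecord],
    fractions: tuple[float, float, float],
    stratified: bool,
    seed: int,
) -> DatasetSplit:
    """Partition records into train/val/test id lists.

    Stratified mode assigns per-label counts by largest remainder so each
    label's proportions track ``fractions`` to within one record. Strata with
    fewer than 3 members go entirely to train (with a warning).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions {fractions} do not sum to 1")
    rng = np.random.default_rng(seed)

    def assign(ids: list[str]) -> tuple[list[str], list[str], list[str]]:
        n = len(ids)
        ids = list(ids)
        rng.shuffle(ids)
        raw = np.array(fractions) * n
        base = np.floor(raw).astype(int)
        rem = raw - base
        for _ in range(n - base.sum()):
            j = int(np.argmax(rem))
            base[j] += 1
            rem[j] = -1.0
        a, b = base[0], base[0] + base[1]
        return ids[:a], ids[a:b], ids[b:]

    if not stratified:
        tr, va, te = assign([r.record_id for r in records])
    else:
        tr, va, te = [], [], []
        by_label: dict[int, list[str]] = defaultdict(list)
        for rec in records:
            by_label[rec.space_group].append(rec.record_id)
        for sg in sorted(by_label):
            ids = by_label[sg]
            if len(ids) < 3:
                warnings.warn(
                    f"stratum for space group {sg} has {len(ids)} < 3 records; "
                    "assigning all to train",
                    stacklevel=2,
                )
                tr.extend(ids)
                continue
            a, b, c = assign(ids)
            tr.extend(a)
            va.extend(b)
            te.extend(c)
    return DatasetSplit(
        train_ids=tr,
        val_ids=va,
        test_ids=te,
        fractions=tuple(fractions),
        seed=seed,
        stratified=stratified,
    )


def curation_predicate(flags: dict) -> bool:
    """Documented stand-in for the upstream structure-database filters.

    Real curation restricts to organic-only, Z' = 1, single-residue entries
    with no ions, polymers or organometallics and no part-molecule asymmetric
    units. Records carry these as boolean metadata flags; synthetic data
    satisfies them trivially. Missing flags are treated as passing.
    """
    required_true = ("organic", "z_prime_one", "single_residue")
    required_false = ("ions", "polymer", "organometallic", "part_molecules")
    return all(flags.get(k, True) for k in required_true) and not any(
        flags.get(k, False) for k in required_false
    )
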