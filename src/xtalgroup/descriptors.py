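"""General, geometric and chemical feature blocks for space-group prediction.

Three named blocks feed the tree-ensemble track:

* general — molecular weight, atom count, ring count, aromatic ring count;
* geometric — inertia-based shape descriptors (normalized principal-moment
  ratios, asphericity, eccentricity), planarity (mean absolute deviation from
  the least-squares plane of best fit) and the point-group operation census;
* chemical — counts of 18 common functional groups (versioned SMARTS pattern
  set) plus topological polar surface area (Ertl atom contributions).

``select_features`` performs the standard redundancy pruning: drop
near-constant columns, then one column of each highly correlated pair. The
fitted selection can be re-applied to a second table so that, e.g., a
selection fitted on a balanced subset is reused on the unbalanced set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

from .dataset import MoleculeRecord, records_to_mol
from .point_symmetry import (
    SYMMETRY_FEATURE_NAMES,
    atomic_masses,
    center_of_mass,
    detect_symmetry,
    inertia_tensor,
    symmetry_features,
)

logger = logging.getLogger(__name__)

GENERAL_FEATURE_NAMES = ("mol_weight", "n_atoms", "n_rings", "n_aromatic_rings")
SHAPE_FEATURE_NAMES = ("npr1", "npr2", "asphericity", "eccentricity", "planarity")


@dataclass
class ShapeDescriptors:
    """Inertia-based molecular shape summary.

    ``npr1 = I1/I3`` and ``npr2 = I2/I3`` (principal moments I1 <= I2 <= I3)
    place the molecule on the rod-disc-sphere triangle; asphericity and
    eccentricity are scalar anisotropy measures; planarity is the mean
    absolute atomic distance (angstrom) from the unweighted least-squares
    plane of best fit.
    """

    npr1: float
    npr2: float
    asphericity: float
    eccentricity: float
    planarity: float
    degenerate_plane: bool = False

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in SHAPE_FEATURE_NAMES}


@dataclass
class FeatureTable:
    """Named numeric feature matrix with per-column class tags."""

    frame: pd.DataFrame
    column_class: dict[str, str]
    geometry_source: str = "optimized"
    selection: list[str] | None = None  # fitted retained-column list

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("feature table contains NaN/Inf")
        missing = set(self.frame.columns) - set(self.column_class)
        if missing:
            raise ValueError(f"columns without class tag: {sorted(missing)}")

    @property
    def row_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def column_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


def general_features(record_or_mol: MoleculeRecord | Chem.Mol) -> dict[str, float]:
    """Molecular weight, atom count (with hydrogens), ring and aromatic-ring counts."""
    if isinstance(record_or_mol, MoleculeRecord):
        mol = records_to_mol(record_or_mol)
    else:
        mol = record_or_mol
    ring_info = mol.GetRingInfo()
    n_aromatic = 0
    for ring in ring_info.BondRings():
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring):
            n_aromatic += 1
    n_atoms = mol.GetNumAtoms() + sum(a.GetNumImplicitHs() for a in mol.GetAtoms())
    return {
        "mol_weight": float(Descriptors.MolWt(mol)),
        "n_atoms": float(n_atoms),
        "n_rings": float(ring_info.NumRings()),
        "n_aromatic_rings": float(n_aromatic),
    }


def shape_descriptors(elements: list[str], coordinates: np.ndarray) -> ShapeDescriptors:
    """Shape descriptors from the mass-weighted inertia tensor and best-fit plane."""
    coords = np.asarray(coordinates, dtype=float)
    if len(coords) < 3:
        raise ValueError("shape descriptors need at least 3 atoms")
    moments = np.linalg.eigvalsh(inertia_tensor(elements, coords))
    i1, i2, i3 = (max(m, 0.0) for m in moments)
    if i3 <= 0:
        raise ValueError("degenerate geometry: zero inertia")
    npr1 = i1 / i3
    npr2 = i2 / i3
    ecc = float(np.sqrt(max(i3 * i3 - i1 * i1, 0.0)) / i3)
    # asphericity follows the gyration-tensor convention of the standard
    # cheminformatics descriptor set: 0.5 * sum (e_i - e_j)^2 / (sum e)^2
    # with mass-weighted gyration eigenvalues (0 = sphere, 1 = rod)
    masses = atomic_masses(elements)
    x = coords - center_of_mass(elements, coords)
    gyr = (masses[:, None, None] * x[:, :, None] * x[:, None, :]).sum(axis=0) / masses.sum()
    e1, e2, e3 = np.linalg.eigvalsh(gyr)
    total = e1 + e2 + e3
    if total <= 0:
        raise ValueError("degenerate geometry: zero gyration")
    asph = 0.5 * ((e1 - e2) ** 2 + (e1 - e3) ** 2 + (e2 - e3) ** 2) / total**2

    centered = coords - coords.mean(axis=0)
    second = centered.T @ centered
    w, v = np.linalg.eigh(second)
    degenerate = bool(w[1] - w[0] < 1e-10 * max(w[2], 1.0))
    normal = v[:, 0]  # smallest principal direction; deterministic under ties
    planarity = float(np.mean(np.abs(centered @ normal)))
    return ShapeDescriptors(
        npr1=float(npr1),
        npr2=float(npr2),
        asphericity=float(asph),
        eccentricity=ecc,
        planarity=planarity,
        degenerate_plane=degenerate,
    )


def _load_patterns() -> list[tuple[str, Chem.Mol]]:
    text = (
        resources.files("xtalgroup").joinpath("data/functional_groups.smarts").read_text()
    )
    patterns = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts = line.split("\t")
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise ValueError(f"bad SMARTS for {name}")
        patterns.append((name, query))
    return patterns


_PATTERNS: list[tuple[str, Chem.Mol]] | None = None


def functional_group_names() -> list[str]:
    global _PATTERNS
    if _PATTERNS is None:
        _PATTERNS = _load_patterns()
    return [name for name, _ in _PATTERNS]


CHEMICAL_FEATURE_NAMES: tuple[str, ...] = tuple(
    ["fg_" + n for n in functional_group_names()] + ["tpsa"]
)


def chemical_features(smiles: str) -> dict[str, float]:
    """18 functional-group counts plus topological polar surface area."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    global _PATTERNS
    if _PATTERNS is None:
        _PATTERNS = _load_patterns()
    out: dict[str, float] = {}
    for name, query in _PATTERNS:
        out["fg_" + name] = float(len(mol.GetSubstructMatches(query, uniquify=True)))
    out["tpsa"] = float(rdMolDescriptors.CalcTPSA(mol))
    return out


GEOMETRIC_FEATURE_NAMES: tuple[str, ...] = SHAPE_FEATURE_NAMES + SYMMETRY_FEATURE_NAMES
ALL_FEATURE_NAMES: tuple[str, ...] = (
    GENERAL_FEATURE_NAMES + GEOMETRIC_FEATURE_NAMES + CHEMICAL_FEATURE_NAMES
)


def feature_classes() -> dict[str, str]:
    classes = {name: "general" for name in GENERAL_FEATURE_NAMES}
    classes.update({name: "geometric" for name in GEOMETRIC_FEATURE_NAMES})
    classes.update({name: "chemical" for name in CHEMICAL_FEATURE_NAMES})
    return classes


def compute_feature_row(record: MoleculeRecord, tolerance: float) -> dict[str, float]:
    mol = records_to_mol(record)
    row = general_features(mol)
    row.update(shape_descriptors(record.elements, record.coordinates).as_dict())
    report = detect_symmetry(record.elements, record.coordinates, tolerance)
    row.update(symmetry_features(report))
    row.update(chemical_features(record.smiles))
    return row


def assemble_features(
    records: Sequence[MoleculeRecord], tolerance: float = 0.05
) -> FeatureTable:
    """Concatenate general + geometric (shape, symmetry) + chemical blocks.

    Records whose descriptor computation fails are excluded with a logged id.
    Identical (smiles, conformer) pairs share a cached row, so polymorph
    families and repeated library molecules cost one computation each.
    """
    rows: dict[str, dict[str, float]] = {}
    cache: dict[tuple, dict[str, float]] = {}
    sources = set()
    for rec in records:
        key = (rec.smiles, rec.coordinates.tobytes())
        try:
            if key not in cache:
                cache[key] = compute_feature_row(rec, tolerance)
            rows[rec.record_id] = cache[key]
            sources.add(rec.geometry_source)
        except (ValueError, RuntimeError) as exc:
            logger.warning("excluding record %s: %s", rec.record_id, exc)
    if not rows:
        raise ValueError("no records survived feature computation")
    frame = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    frame = frame[list(ALL_FEATURE_NAMES)]
    source = sources.pop() if len(sources) == 1 else "mixed"
    return FeatureTable(frame=frame, column_class=feature_classes(), geometry_source=source)


def select_features(
    table: FeatureTable,
    corr_threshold: float = 0.9,
    var_threshold: float = 1e-8,
    selection: list[str] | None = None,
) -> FeatureTable:
    """Remove low-variance columns, then one column of each high-|r| pair.

    With ``selection`` given (the retained-column list from a previous fit),
    the same columns are kept instead of refitting — so a selection fitted on
    one dataset variant can be applied verbatim to another.
    """
    if selection is None:
        if len(table.frame) < 2:
            raise ValueError("need >= 2 rows to fit a selection")
        frame = table.frame
        keep = [c for c in frame.columns if float(frame[c].var(ddof=0)) >= var_threshold]
        if keep:
            corr = frame[keep].corr().abs().to_numpy()
            retained: list[int] = []
            for j in range(len(keep)):
                if all(corr[j, i] <= corr_threshold for i in retained):
                    retained.append(j)
            keep = [keep[j] for j in retained]
        if not keep:
            raise ValueError("feature selection removed every column")
        selection = keep
    missing = set(selection) - set(table.frame.columns)
    if missing:
        raise ValueError(f"selection references absent columns: {sorted(missing)}")
    frame = table.frame[list(selection)]
    classes = {c: table.column_class[c] for c in selection}
    return FeatureTable(
        frame=frame,
        column_class=classes,
        geometry_source=table.geometry_source,
        selection=list(selection),
    )
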