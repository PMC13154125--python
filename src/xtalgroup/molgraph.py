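"""Attributed molecular graphs for the graph-network track, plus rotation augmentation.

Node attributes: atomic number, hybridization one-hot (sp/sp2/sp3/other),
formal charge, aromatic flag, Gasteiger partial charge. Edge attributes
(each bond stored as two directed edges): bond-order one-hot
(single/double/triple/aromatic), conjugated flag, in-ring flag. Atomic
coordinates are attached optionally; topology and attributes other than
coordinates are invariant to rigid motion of the conformer.

``augment_batch`` implements rotation-based data augmentation: each graph is
emitted four times — the original, plus one copy rotated about each of the
x, y and z axes by an independent uniform angle — so a batch of 16 becomes 64.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .dataset import MoleculeRecord, records_to_mol

NODE_DIM = 8   # Z, 4x hybridization, formal charge, aromatic, Gasteiger charge
EDGE_DIM = 6   # 4x bond order, conjugated, in-ring

_HYBRID = {
    Chem.HybridizationType.SP: 0,
    Chem.HybridizationType.SP2: 1,
    Chem.HybridizationType.SP3: 2,
}
_BOND = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


@dataclass
class MolecularGraph:
    node_attrs: np.ndarray            # (n_nodes, NODE_DIM)
    edge_index: np.ndarray            # (2, n_edges) directed, symmetric
    edge_attrs: np.ndarray            # (n_edges, EDGE_DIM)
    label: int                        # space-group class index
    coordinates: np.ndarray | None = None  # (n_nodes, 3), optional
    record_id: str = ""

    def __post_init__(self) -> None:
        fwd = {(int(u), int(v)) for u, v in self.edge_index.T}
        if {(v, u) for u, v in fwd} != fwd:
            raise ValueError("edge_index is not symmetric")

    @property
    def n_nodes(self) -> int:
        return self.node_attrs.shape[0]


def build_graph(
    record: MoleculeRecord,
    include_coordinates: bool = True,
    explicit_hydrogens: bool = True,
    label_index: int | None = None,
) -> MolecularGraph:
    """Build the attributed graph for one record.

    Hydrogens are explicit nodes by default (hydrogen bonding matters for
    packing); pass ``explicit_hydrogens=False`` for heavy-atom graphs.
    """
    mol = records_to_mol(record)
    coords = np.asarray(record.coordinates, dtype=float)
    if not explicit_hydrogens:
        keep = [i for i, a in enumerate(mol.GetAtoms()) if a.GetAtomicNum() != 1]
        coords = coords[keep]
        mol = Chem.RemoveHs(mol)
    AllChem.ComputeGasteigerCharges(mol)

    n = mol.GetNumAtoms()
    nodes = np.zeros((n, NODE_DIM))
    total_formal = 0
    for i, atom in enumerate(mol.GetAtoms()):
        nodes[i, 0] = atom.GetAtomicNum()
        nodes[i, 1 + _HYBRID.get(atom.GetHybridization(), 3)] = 1.0
        nodes[i, 5] = atom.GetFormalCharge()
        nodes[i, 6] = 1.0 if atom.GetIsAromatic() else 0.0
        q = atom.GetDoubleProp("_GasteigerCharge")
        if not explicit_hydrogens and atom.HasProp("_GasteigerHCharge"):
            q += atom.GetDoubleProp("_GasteigerHCharge")  # fold implicit-H charge in
        if not np.isfinite(q):
            raise ValueError(f"Gasteiger charge failed for {record.record_id}")
        nodes[i, 7] = q
    total_formal = sum(a.GetFormalCharge() for a in mol.GetAtoms())
    if abs(nodes[:, 7].sum() - total_formal) > 1e-3:
        raise ValueError(f"Gasteiger charges do not sum to formal charge for {record.record_id}")

    src, dst, eattrs = [], [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        attr = np.zeros(EDGE_DIM)
        attr[_BOND.get(bond.GetBondType(), 0)] = 1.0
        attr[4] = 1.0 if bond.GetIsConjugated() else 0.0
        attr[5] = 1.0 if bond.IsInRing() else 0.0
        for a, b in ((u, v), (v, u)):
            src.append(a)
            dst.append(b)
            eattrs.append(attr)
    return MolecularGraph(
        node_attrs=nodes,
        edge_index=np.array([src, dst], dtype=int),
        edge_attrs=np.array(eattrs),
        label=record.space_group if label_index is None else label_index,
        coordinates=coords if include_coordinates else None,
        record_id=record.record_id,
    )


def _axis_rotation(axis: int, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    r = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    r[i, i] = c
    r[j, j] = c
    r[i, j] = -s if axis != 1 else s
    r[j, i] = s if axis != 1 else -s
    return r


def augment_batch(graphs: list[MolecularGraph], seed: int) -> list[MolecularGraph]:
    """Emit 4 graphs per input: the original plus x-, y- and z-axis rotations.

    Each rotated copy uses an independent uniform angle in [0, 2pi); labels
    and topology are unchanged, so a batch of 16 becomes 64.
    """
    rng = np.random.default_rng(seed)
    out: list[MolecularGraph] = []
    for g in graphs:
        if g.coordinates is None:
            raise ValueError(f"graph {g.record_id or '?'} has no coordinates to rotate")
        out.append(g)
        for axis in range(3):
            r = _axis_rotation(axis, float(rng.uniform(0.0, 2.0 * np.pi)))
            out.append(replace(g, coordinates=g.coordinates @ r.T))
    return out
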