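"""Molecular point-group detection and symmetry-operation census.

Counts the point-group operations of a 3D conformer: identity, proper
rotations Cn, reflections, inversion and improper rotations Sn, with each
distinct operation counted individually (C3 and C3^2 are two operations), so
the total equals the point-group order for a non-linear molecule.

Algorithm. Coordinates are centered at the center of mass (standard atomic
weights). Any symmetry axis or mirror normal of the point set must be an
eigenvector of the inertia tensor; when the principal moments are
non-degenerate only the three principal axes are candidates, and under
degeneracy the candidate set is widened with atom position vectors, pair sums
(C2 bisectors) and pair differences (mirror normals for atom-swapping
reflections). A candidate orthogonal transform is accepted when it maps the
element-labeled point set onto itself with maximum displacement below the
tolerance (optimal per-element matching via the Hungarian algorithm). Each
accepted operation is identified by the atom permutation it induces together
with its determinant sign — a pair that determines the operation uniquely for
non-linear molecules — then canonicalized by constrained Kabsch superposition
and classified by its rotation angle.

Linear molecules have a continuous rotation axis; their census is computed
analytically with rotation orders capped at ``n_max`` and flagged ``linear``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

_PT = Chem.GetPeriodicTable()

DEFAULT_TOLERANCE = 0.05  # angstrom, suited to relaxed geometries
CRYSTAL_TOLERANCE = 0.1   # documented looser alternative for crystal geometries
N_MAX = 8

# Fixed census schema (absent classes reported as 0).
OPERATOR_CLASSES: tuple[str, ...] = (
    "E",
    *(f"C{n}" for n in range(2, N_MAX + 1)),
    "sigma",
    "i",
    *(f"S{n}" for n in range(3, N_MAX + 1)),
)

_DEGENERACY_RTOL = 0.05
_ANGLE_ATOL = 0.12  # rad; classification slack for tolerance-level distortion


@dataclass
class SymmetryReport:
    total_operations: int
    count_by_class: dict[str, int]
    point_group_name: str
    tolerance: float
    linear: bool = False

    def __post_init__(self) -> None:
        if self.count_by_class.get("E", 0) != 1:
            raise ValueError("census must contain exactly one identity")
        if self.total_operations != sum(self.count_by_class.values()):
            raise ValueError("total_operations does not match class counts")


def atomic_masses(elements: list[str]) -> np.ndarray:
    return np.array([_PT.GetAtomicWeight(e) for e in elements])


def center_of_mass(elements: list[str], coords: np.ndarray) -> np.ndarray:
    m = atomic_masses(elements)
    return (m[:, None] * coords).sum(axis=0) / m.sum()


def inertia_tensor(elements: list[str], coords: np.ndarray) -> np.ndarray:
    """Mass-weighted inertia tensor about the center of mass."""
    m = atomic_masses(elements)
    x = coords - center_of_mass(elements, coords)
    r2 = (x**2).sum(axis=1)
    eye = np.eye(3)
    return (m[:, None, None] * (r2[:, None, None] * eye - x[:, :, None] * x[:, None, :])).sum(
        axis=0
    )


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _reflection(normal: np.ndarray) -> np.ndarray:
    n = normal / np.linalg.norm(normal)
    return np.eye(3) - 2.0 * np.outer(n, n)


def _match_permutation(
    x: np.ndarray, y: np.ndarray, element_groups: list[np.ndarray], tol: float
) -> np.ndarray | None:
    """Optimal element-preserving matching of transformed coords ``y`` onto ``x``.

    Returns perm with x[perm[i]] ~ y[i], or None if max displacement > tol.
    """
    n = len(x)
    perm = np.empty(n, dtype=int)
    for idx in element_groups:
        d = cdist(y[idx], x[idx])
        # cheap reject before the Hungarian solve
        if d.min(axis=1).max() > tol:
            return None
        rows, cols = linear_sum_assignment(d)
        if d[rows, cols].max() > tol:
            return None
        perm[idx] = idx[cols]
    return perm


def _kabsch_fixed_det(x: np.ndarray, y: np.ndarray, det_sign: float) -> np.ndarray:
    """Orthogonal R with sign(det R) = det_sign minimizing ||x @ R.T - y||."""
    a = x.T @ y
    u, _, vt = np.linalg.svd(a)
    v = vt.T
    d = det_sign * np.sign(np.linalg.det(v @ u.T))
    return v @ np.diag([1.0, 1.0, d]) @ u.T


def _dedupe_directions(vecs: list[np.ndarray], min_norm: float = 1e-6) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for v in vecs:
        nv = np.linalg.norm(v)
        if nv < min_norm:
            continue
        u = v / nv
        if any(abs(abs(u @ w) - 1.0) < 1e-6 for w in out):
            continue
        out.append(u)
    return out


def _candidate_axes(x: np.ndarray, moments: np.ndarray, axes: np.ndarray) -> list[np.ndarray]:
    cands = [axes[:, i] for i in range(3)]
    scale = max(moments[-1], 1e-12)
    degenerate = (
        (moments[1] - moments[0]) / scale < _DEGENERACY_RTOL
        or (moments[2] - moments[1]) / scale < _DEGENERACY_RTOL
    )
    if degenerate:
        cands.extend(x)
        for i, j in itertools.combinations(range(len(x)), 2):
            cands.append(x[i] + x[j])
            cands.append(x[i] - x[j])
    return _dedupe_directions(cands)


def _classify(r: np.ndarray) -> str:
    det = np.linalg.det(r)
    tr = float(np.trace(r))
    if det > 0:
        cos = min(1.0, max(-1.0, (tr - 1.0) / 2.0))
        theta = math.acos(cos)
        if theta < _ANGLE_ATOL:
            return "E"
        return f"C{_angle_order(theta)}"
    cos = min(1.0, max(-1.0, (tr + 1.0) / 2.0))
    theta = math.acos(cos)
    if theta < _ANGLE_ATOL:
        return "sigma"
    if abs(theta - math.pi) < _ANGLE_ATOL:
        return "i"
    return f"S{_angle_order(theta)}"


def _angle_order(theta: float) -> int:
    best_n, best_err = 2, float("inf")
    for n in range(2, N_MAX + 1):
        for k in range(1, n):
            if math.gcd(k, n) != 1:
                continue
            err = abs(theta - 2 * math.pi * k / n)
            if err < best_err - 1e-12:
                best_err, best_n = err, n
    return best_n


def _op_axis(r: np.ndarray) -> np.ndarray:
    """Rotation axis (proper) or mirror/improper axis (improper) of an operation."""
    target = 1.0 if np.linalg.det(r) > 0 else -1.0
    w, v = np.linalg.eig(r)
    i = int(np.argmin(np.abs(w - target)))
    axis = np.real(v[:, i])
    return axis / np.linalg.norm(axis)


def _euler_phi_total(n_max: int) -> dict[int, int]:
    return {n: sum(1 for k in range(1, n) if math.gcd(k, n) == 1) for n in range(2, n_max + 1)}


def _linear_census(elements: list[str], x: np.ndarray, tol: float) -> SymmetryReport:
    """Capped census for a linear molecule (continuous axis -> orders <= N_MAX)."""
    # axis = dominant principal direction of the coordinate second moment
    _, _, vt = np.linalg.svd(x - x.mean(axis=0))
    axis = vt[0]
    t = x @ axis
    order = np.argsort(t)
    rev = order[::-1]
    # centrosymmetric profile: element sequence and positions palindromic
    sym = all(elements[order[i]] == elements[rev[i]] for i in range(len(t))) and np.allclose(
        t[order], -t[rev], atol=tol
    )
    phi = _euler_phi_total(N_MAX)
    counts = {c: 0 for c in OPERATOR_CLASSES}
    counts["E"] = 1
    for n in range(2, N_MAX + 1):
        counts[f"C{n}"] += phi[n]          # rotations about the molecular axis
    counts["sigma"] += N_MAX               # sigma_v planes, capped
    if sym:
        counts["C2"] += N_MAX              # perpendicular C2 axes, capped
        counts["sigma"] += 1               # sigma_h
        counts["i"] += 1
        for n in range(3, N_MAX + 1):
            counts[f"S{n}"] += phi[n]
    name = "Dinfh" if sym else "Cinfv"
    return SymmetryReport(
        total_operations=sum(counts.values()),
        count_by_class=counts,
        point_group_name=name,
        tolerance=tol,
        linear=True,
    )


def detect_symmetry(
    elements: list[str], coordinates: np.ndarray, tolerance: float = DEFAULT_TOLERANCE
) -> SymmetryReport:
    """Census of point-group operations mapping the conformer onto itself.

    Parameters
    ----------
    elements : element symbols, one per atom.
    coordinates : (n_atoms, 3) Cartesian angstroms.
    tolerance : maximum displacement (angstrom) for an operation to count.
    """
    x = np.asarray(coordinates, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or len(x) != len(elements) or len(x) < 2:
        raise ValueError("need >= 2 atoms with (n, 3) coordinates")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    x = x - center_of_mass(elements, x)
    if np.max(np.linalg.norm(x, axis=1)) < 1e-8:
        raise ValueError("degenerate geometry: all atoms coincident")

    # linear if perpendicular spread from the best-fit line is below tolerance
    u, s, vt = np.linalg.svd(x - x.mean(axis=0))
    perp = np.linalg.norm(x - np.outer(x @ vt[0], vt[0]), axis=1).max()
    if perp <= max(tolerance, 1e-8):
        return _linear_census(elements, x, tolerance)

    uniq = sorted(set(elements))
    element_groups = [np.array([i for i, e in enumerate(elements) if e == el]) for el in uniq]

    moments, paxes = np.linalg.eigh(inertia_tensor(elements, x))
    axes = _candidate_axes(x, moments, paxes)

    # discover operations; key = (induced permutation, det sign)
    found: dict[tuple[tuple[int, ...], int], np.ndarray] = {}
    ident = tuple(range(len(x)))
    found[(ident, 1)] = np.eye(3)

    def try_op(r: np.ndarray) -> None:
        perm = _match_permutation(x, x @ r.T, element_groups, tolerance)
        if perm is None:
            return
        key = (tuple(perm), 1 if np.linalg.det(r) > 0 else -1)
        if key in found:
            return
        canon = _kabsch_fixed_det(x, x[perm], float(key[1]))
        resid = np.linalg.norm(x @ canon.T - x[perm], axis=1).max()
        found[key] = canon if resid <= tolerance else r

    try_op(-np.eye(3))
    for ax in axes:
        try_op(_reflection(ax))
        for n in range(2, N_MAX + 1):
            for k in range(1, n):
                rot = _rotation(ax, 2 * math.pi * k / n)
                try_op(rot)
                try_op(_reflection(ax) @ rot)

    counts = {c: 0 for c in OPERATOR_CLASSES}
    ops: list[tuple[str, np.ndarray]] = []
    for key, r in found.items():
        cls = "E" if key == (ident, 1) else _classify(r)
        counts[cls] = counts.get(cls, 0) + 1
        ops.append((cls, r))
    total = sum(counts.values())
    name = _point_group_name(counts, ops)
    return SymmetryReport(
        total_operations=total,
        count_by_class=counts,
        point_group_name=name,
        tolerance=tolerance,
        linear=False,
    )


def _point_group_name(counts: dict[str, int], ops: list[tuple[str, np.ndarray]]) -> str:
    """Best-effort Schoenflies symbol from the operation census."""
    total = sum(counts.values())
    if total == 1:
        return "C1"
    if total == 2:
        if counts["i"]:
            return "Ci"
        if counts["sigma"]:
            return "Cs"
        return "C2"
    n_c3_axes = len(
        _dedupe_directions([_op_axis(r) for cls, r in ops if cls == "C3"])
    )
    if n_c3_axes >= 4:  # cubic/icosahedral family
        if counts.get("C5", 0):
            return "Ih" if counts["i"] else "I"
        if counts["i"]:
            return "Oh" if total == 48 else "Th"
        return "Td" if counts["sigma"] else "O"
    # principal axis = highest rotation order
    n_princ = 1
    for n in range(N_MAX, 1, -1):
        if counts.get(f"C{n}", 0):
            n_princ = n
            break
    if n_princ == 1:
        if counts["sigma"]:
            return "Cs"
        return "Ci" if counts["i"] else "C1"
    princ_axes = [_op_axis(r) for cls, r in ops if cls == f"C{n_princ}"]
    principal = princ_axes[0]
    c2_axes = _dedupe_directions([_op_axis(r) for cls, r in ops if cls == "C2"])
    n_perp_c2 = sum(1 for a in c2_axes if abs(a @ principal) < 0.1)
    sigma_normals = [_op_axis(r) for cls, r in ops if cls == "sigma"]
    has_sigma_h = any(abs(nrm @ principal) > 0.9 for nrm in sigma_normals)
    n_sigma_v = sum(1 for nrm in sigma_normals if abs(nrm @ principal) < 0.1)
    if n_perp_c2 >= n_princ:
        if has_sigma_h:
            return f"D{n_princ}h"
        if n_sigma_v >= n_princ:
            return f"D{n_princ}d"
        return f"D{n_princ}"
    if has_sigma_h:
        return f"C{n_princ}h"
    if n_sigma_v >= n_princ:
        return f"C{n_princ}v"
    if counts.get(f"S{2 * n_princ}", 0):
        return f"S{2 * n_princ}"
    return f"C{n_princ}"


SYMMETRY_FEATURE_NAMES: tuple[str, ...] = ("n_sym_ops",) + tuple(
    f"sym_{c}" for c in OPERATOR_CLASSES
)


def symmetry_features(report: SymmetryReport) -> dict[str, float]:
    """Fixed-schema feature vector: total operation count then per-class counts."""
    out = {"n_sym_ops": float(report.total_operations)}
    for c in OPERATOR_CLASSES:
        out[f"sym_{c}"] = float(report.count_by_class.get(c, 0))
    return out
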