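"""Independent brute-force oracles used only by the tests.

These deliberately avoid the candidate-generation machinery of the package:
the symmetry oracle enumerates element-preserving atom permutations directly
(with distance-compatibility pruning) and accepts those realizable by an
orthogonal transform via constrained Kabsch superposition; the metric oracle
is a literal per-example tally of the 1/N-scaled precision/recall rules.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist

from xtalgroup.point_symmetry import center_of_mass


def _kabsch(x: np.ndarray, y: np.ndarray, det_sign: float) -> np.ndarray:
    a = x.T @ y
    u, _, vt = np.linalg.svd(a)
    v = vt.T
    d = det_sign * np.sign(np.linalg.det(v @ u.T))
    return v @ np.diag([1.0, 1.0, d]) @ u.T


def brute_force_symmetry_count(
    elements: list[str], coordinates: np.ndarray, tolerance: float
) -> int:
    """Count (permutation, determinant-sign) pairs realizable within tolerance.

    For a non-linear molecule this equals the point-group order: a realizable
    permutation determines the orthogonal transform up to the choice of
    determinant sign (two transforms only when the atoms are coplanar).
    """
    x = np.asarray(coordinates, dtype=float) - center_of_mass(elements, coordinates)
    n = len(x)
    dmat = squareform(pdist(x))
    radii = np.linalg.norm(x, axis=1)
    same_element = np.array([[ei == ej for ej in elements] for ei in elements])

    # candidate images: same element, compatible distance from the center
    allowed = [
        [j for j in range(n) if same_element[i][j] and abs(radii[i] - radii[j]) <= 2 * tolerance]
        for i in range(n)
    ]

    perms: list[np.ndarray] = []

    def backtrack(i: int, perm: list[int], used: set[int]) -> None:
        if i == n:
            perms.append(np.array(perm))
            return
        for j in allowed[i]:
            if j in used:
                continue
            # pairwise distances must be preserved against all assigned atoms
            if all(abs(dmat[i, k] - dmat[j, perm[k]]) <= 2 * tolerance for k in range(i)):
                perm.append(j)
                used.add(j)
                backtrack(i + 1, perm, used)
                perm.pop()
                used.remove(j)

    backtrack(0, [], set())

    count = 0
    for perm in perms:
        for det_sign in (1.0, -1.0):
            r = _kabsch(x, x[perm], det_sign)
            if np.sign(np.linalg.det(r)) != det_sign:
                continue
            if np.linalg.norm(x @ r.T - x[perm], axis=1).max() <= tolerance:
                count += 1
    return count


def naive_scaled_tally(truths, predictions):
    """Literal restatement of the scaled precision/recall rules."""
    classes = set(truths)
    for p in predictions:
        classes.update(p)
    tp = {c: 0.0 for c in classes}
    fp = {c: 0.0 for c in classes}
    fn = {c: 0.0 for c in classes}
    for t, preds in zip(truths, predictions):
        n = len(preds)
        if t in preds:
            tp[t] += 1.0
        else:
            fn[t] += 1.0
        for h in preds:
            if h != t:
                fp[h] += 1.0 / n
    out = {}
    for c in classes:
        recall = tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] > 0 else None
        precision = tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] > 0 else None
        out[c] = dict(tp=tp[c], fp=fp[c], fn=fn[c], recall=recall, precision=precision)
    return out
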