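"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: the Jacobi eigensolver
uses plane rotations instead of LAPACK, and the correlation oracle expands
the covariance/sd definition elementwise.
"""

from __future__ import annotations

import numpy as np


def jacobi_eigh(a: np.ndarray, tol: float = 1e-14, max_sweeps: int = 100):
    """Eigenvalues/vectors of a small symmetric matrix by cyclic Jacobi
    rotations.  Returns (eigenvalues, eigenvectors) sorted descending."""
    a = np.array(a, dtype=float)
    n = a.shape[0]
    v = np.eye(n)
    for _ in range(max_sweeps):
        off = np.sqrt(np.sum(np.tril(a, -1) ** 2))
        if off < tol:
            break
        for p in range(n - 1):
            for q in range(p + 1, n):
                if abs(a[p, q]) < tol * 1e-3:
                    continue
                theta = 0.5 * np.arctan2(2 * a[p, q], a[q, q] - a[p, p])
                c, s = np.cos(theta), np.sin(theta)
                rot = np.eye(n)
                rot[p, p] = c
                rot[q, q] = c
                rot[p, q] = s
                rot[q, p] = -s
                a = rot.T @ a @ rot
                v = v @ rot
    eig = np.diag(a).copy()
    order = np.argsort(-eig, kind="stable")
    return eig[order], v[:, order]


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation from the elementwise definition."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum() / len(x)
    sx = np.sqrt(((x - mx) ** 2).sum() / len(x))
    sy = np.sqrt(((y - my) ** 2).sum() / len(y))
    return cov / (sx * sy)


def overlap_oracle(sets: dict) -> dict:
    """Directional Venn regions by direct enumeration.

    ``sets``: label -> {gene: direction}.  Returns (regions, discordant)
    keyed by frozenset of labels.
    """
    regions: dict = {}
    discordant: dict = {}
    union = set()
    for members in sets.values():
        union |= set(members)
    for gene in union:
        labels = frozenset(lbl for lbl, mem in sets.items() if gene in mem)
        dirs = {sets[lbl][gene] for lbl in labels}
        target = regions if len(dirs) == 1 else discordant
        target[labels] = target.get(labels, 0) + 1
    return regions, discordant
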