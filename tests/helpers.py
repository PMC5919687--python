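"""Independent oracles and small utilities shared by the test suite.

These deliberately avoid the implementation paths they check: the global
aligner is re-derived as a plain Gotoh dynamic program with exhaustive
traceback, superposition is redone with Horn's quaternion method, and the
Mann-Whitney U null is enumerated over all group assignments.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN = -10.0
GAP_EXTEND = -0.5


def gotoh_matrices(a: str, b: str):
    """Affine-gap global alignment DP (Gotoh), three-state."""
    n, m = len(a), len(b)
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (a aligned to '-')
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            X[i, j] = max(
                M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND,
                Y[i - 1, j] + GAP_OPEN,
            )
            Y[i, j] = max(
                M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND,
                X[i, j - 1] + GAP_OPEN,
            )
    return M, X, Y


def gotoh_score(a: str, b: str) -> float:
    M, X, Y = gotoh_matrices(a, b)
    return float(max(M[-1, -1], X[-1, -1], Y[-1, -1]))


def enumerate_optimal_alignments(a: str, b: str, cap: int = 200):
    """All co-optimal global alignments as (row_a, row_b) gapped strings."""
    M, X, Y = gotoh_matrices(a, b)
    eps = 1e-9
    out = []

    def walk(i, j, state, col_a, col_b):
        if len(out) >= cap:
            return
        if i == 0 and j == 0:
            out.append(("".join(reversed(col_a)), "".join(reversed(col_b))))
            return
        if state == "M":
            s = BLOSUM62[a[i - 1], b[j - 1]]
            for prev, mat in (("M", M), ("X", X), ("Y", Y)):
                if abs(mat[i - 1, j - 1] + s - M[i, j]) < eps:
                    walk(i - 1, j - 1, prev, col_a + [a[i - 1]], col_b + [b[j - 1]])
        elif state == "X":
            if i == 0:
                return
            if abs(M[i - 1, j] + GAP_OPEN - X[i, j]) < eps:
                walk(i - 1, j, "M", col_a + [a[i - 1]], col_b + ["-"])
            if abs(X[i - 1, j] + GAP_EXTEND - X[i, j]) < eps:
                walk(i - 1, j, "X", col_a + [a[i - 1]], col_b + ["-"])
            if abs(Y[i - 1, j] + GAP_OPEN - X[i, j]) < eps:
                walk(i - 1, j, "Y", col_a + [a[i - 1]], col_b + ["-"])
        else:
            if j == 0:
                return
            if abs(M[i, j - 1] + GAP_OPEN - Y[i, j]) < eps:
                walk(i, j - 1, "M", col_a + ["-"], col_b + [b[j - 1]])
            if abs(Y[i, j - 1] + GAP_EXTEND - Y[i, j]) < eps:
                walk(i, j - 1, "Y", col_a + ["-"], col_b + [b[j - 1]])
            if abs(X[i, j - 1] + GAP_OPEN - Y[i, j]) < eps:
                walk(i, j - 1, "X", col_a + ["-"], col_b + [b[j - 1]])

    final = max(M[-1, -1], X[-1, -1], Y[-1, -1])
    for state, mat in (("M", M), ("X", X), ("Y", Y)):
        if abs(mat[-1, -1] - final) < eps:
            walk(len(a), len(b), state, [], [])
    return out


def identity_of_alignment(row_a: str, row_b: str) -> float:
    """Percent identity, terminal-gap overhangs excluded (oracle copy of
    the documented identity definition, computed independently)."""
    n = len(row_a)
    start, end = 0, n
    while start < n and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    core = list(zip(row_a[start:end], row_b[start:end]))
    if not core:
        return 0.0
    same = sum(1 for x, y in core if x == y and x != "-")
    return 100.0 * same / len(core)


# ---------------------------------------------------------------------------

def mwu_exact(x, y):
    """Exact two-sided Mann-Whitney U by full enumeration (tie-free)."""
    x, y = list(x), list(y)
    pooled = x + y
    n, m = len(x), len(y)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    all_ranks = sorted(ranks[v] for v in pooled)
    us = [
        sum(all_ranks[i] for i in combo) - n * (n + 1) / 2
        for combo in itertools.combinations(range(n + m), n)
    ]
    total = comb(n + m, n)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------

def quaternion_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Optimal superposition RMSD via Horn's quaternion method."""
    A = np.asarray(A, float) - np.mean(A, axis=0)
    B = np.asarray(B, float) - np.mean(B, axis=0)
    Sxx = A.T @ B
    (sxx, sxy, sxz), (syx, syy, syz), (szx, szy, szz) = Sxx
    K = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(A ** 2) + np.sum(B ** 2) - 2.0 * lam) / len(A)
    return float(np.sqrt(max(msd, 0.0)))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def rigid_transform_chain(chain, rng: np.random.Generator):
    """Apply one random rotation + translation to every atom of a chain."""
    from aars_motifs.structure import Atom, copy_chain

    R = random_rotation(rng)
    t = rng.uniform(-20, 20, size=3)
    out = copy_chain(chain)
    for res in out.residues:
        res.atoms = [
            Atom(a.name, a.element, tuple(R @ a.xyz + t)) for a in res.atoms
        ]
    for lig in out.ligands:
        lig.atoms = [
            Atom(a.name, a.element, tuple(R @ a.xyz + t)) for a in lig.atoms
        ]
    return out
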