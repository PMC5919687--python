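"""Geometric descriptors of motif occurrences and binding-mode comparison.

Two descriptors characterise a two-residue motif: the Euclidean distance
between the alpha carbons, and the side-chain angle theta between the two
vectors that run from each residue's CA to its most distant side-chain
carbon atom. Theta is undefined when a residue is glycine or exposes no
side-chain carbon. Adenosine-phosphate-bound (M1) and unbound (M2)
observations are summarised separately and compared with a two-sided
Mann-Whitney U test. Motif backbones are superposed pairwise with a
least-squares (Kabsch) fit.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .dataset import BindingMode
from .structure import Residue

BACKBONE_SCOPE = ("N", "CA", "C", "O")


@dataclass
class MotifObservation:
    structure_id: str
    chain_id: str
    motif_name: str
    positions: tuple[int, int]
    ca_distance: float
    theta: float | None
    binding_mode: BindingMode

    def __post_init__(self):
        if self.ca_distance <= 0:
            raise ValueError("ca_distance must be positive")
        if self.theta is not None and not 0.0 <= self.theta <= 180.0:
            raise ValueError("theta must lie in [0, 180]")


def ca_distance(res_a: Residue, res_b: Residue) -> float:
    """Euclidean distance (A) between the two alpha carbons."""
    ca_a, ca_b = res_a.ca, res_b.ca
    if ca_a is None or ca_b is None:
        raise ValueError(
            f"missing CA atom in {res_a.label if ca_a is None else res_b.label}"
        )
    return float(np.linalg.norm(ca_a.xyz - ca_b.xyz))


def side_chain_vector(residue: Residue) -> np.ndarray | None:
    """Vector from CA to the most distant side-chain carbon, or None.

    Backbone carbons (C, CA) are excluded; glycine and residues with no
    resolved side-chain carbon yield None. Distance ties break toward the
    lexicographically smallest atom name.
    """
    if residue.name.upper() == "GLY":
        return None
    ca = residue.ca
    if ca is None:
        return None
    candidates = [
        a for a in residue.atoms
        if a.element.upper() == "C" and a.name not in ("C", "CA")
    ]
    if not candidates:
        return None
    best = max(
        candidates,
        key=lambda a: (np.linalg.norm(a.xyz - ca.xyz), [-ord(c) for c in a.name]),
    )
    vec = best.xyz - ca.xyz
    if np.linalg.norm(vec) == 0:
        return None
    return vec


def side_chain_angle(res_a: Residue, res_b: Residue) -> float | None:
    """Angle theta (degrees, [0, 180]) between the two side-chain vectors."""
    va, vb = side_chain_vector(res_a), side_chain_vector(res_b)
    if va is None or vb is None:
        return None
    cosine = np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
    return float(np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0))))


def observe_motif(
    structure_id: str,
    chain_id: str,
    motif_name: str,
    positions: tuple[int, int],
    res_a: Residue,
    res_b: Residue,
    binding_mode: BindingMode,
) -> MotifObservation:
    return MotifObservation(
        structure_id=structure_id,
        chain_id=chain_id,
        motif_name=motif_name,
        positions=positions,
        ca_distance=ca_distance(res_a, res_b),
        theta=side_chain_angle(res_a, res_b),
        binding_mode=binding_mode,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U

def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (statistic for x) and p-value.

    Exact null enumeration for small tie-free samples (both n <= 20),
    tie-corrected normal approximation otherwise.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 20 and len(y) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupStats:
    n: int
    mean: float
    sd: float


@dataclass
class GeometrySummary:
    """Per (motif, binding mode) descriptor statistics and M1-vs-M2 tests."""

    distance: dict[str, GroupStats] = field(default_factory=dict)
    theta: dict[str, GroupStats] = field(default_factory=dict)
    distance_test: tuple[float, float] | None = None
    theta_test: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        def grp(d):
            return {k: vars(v) for k, v in d.items()}

        return {
            "distance": grp(self.distance),
            "theta": grp(self.theta),
            "distance_test": self.distance_test,
            "theta_test": self.theta_test,
        }


def _stats(values: list[float]) -> GroupStats | None:
    if not values:
        return None
    arr = np.asarray(values, float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return GroupStats(n=len(arr), mean=float(arr.mean()), sd=sd)


def summarize_geometry(observations: Sequence[MotifObservation]) -> GeometrySummary:
    """Group descriptive statistics by binding mode; Mann-Whitney M1 vs M2.

    Undefined thetas are excluded listwise from the theta statistics while
    their distances are kept. Tests require at least 3 defined values per
    group.
    """
    summary = GeometrySummary()
    dist = {m: [] for m in ("M1", "M2")}
    theta = {m: [] for m in ("M1", "M2")}
    for obs in observations:
        mode = obs.binding_mode.value
        dist[mode].append(obs.ca_distance)
        if obs.theta is not None:
            theta[mode].append(obs.theta)
    for mode in ("M1", "M2"):
        s = _stats(dist[mode])
        if s:
            summary.distance[mode] = s
        s = _stats(theta[mode])
        if s:
            summary.theta[mode] = s
    if len(dist["M1"]) >= 3 and len(dist["M2"]) >= 3:
        summary.distance_test = mann_whitney_u(dist["M1"], dist["M2"])
    if len(theta["M1"]) >= 3 and len(theta["M2"]) >= 3:
        summary.theta_test = mann_whitney_u(theta["M1"], theta["M2"])
    return summary


# ---------------------------------------------------------------------------
# rigid superposition

def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD after optimal least-squares rigid superposition (Kabsch)."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must share shape (n, 3)")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    diff = (rot @ ac.T).T - bc
    return float(np.sqrt((diff ** 2).sum() / len(a)))


def motif_backbone_coords(
    res_a: Residue, res_b: Residue, atom_scope: Sequence[str] = BACKBONE_SCOPE
) -> np.ndarray | None:
    """Stacked backbone coordinates of both residues, or None if incomplete."""
    pts = []
    for res in (res_a, res_b):
        for name in atom_scope:
            atom = res.atom(name)
            if atom is None:
                return None
            pts.append(atom.xyz)
    return np.array(pts)


def superpose_motifs(
    coord_sets: Sequence[np.ndarray],
) -> tuple[np.ndarray, float]:
    """All-vs-all pairwise Kabsch RMSD matrix and its mean over pairs."""
    n = len(coord_sets)
    matrix = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        r = kabsch_rmsd(coord_sets[i], coord_sets[j])
        matrix[i, j] = matrix[j, i] = r
    pairs = [matrix[i, j] for i, j in itertools.combinations(range(n), 2)]
    mean = float(np.mean(pairs)) if pairs else 0.0
    return matrix, mean


# ---------------------------------------------------------------------------
# observation I/O

def write_observations(
    observations: Sequence[MotifObservation], path: str | Path
) -> None:
    lines = ["pdb_id\tchain\tmotif\tmode\tca_distance\ttheta"]
    for o in observations:
        theta = "" if o.theta is None else f"{o.theta:.4f}"
        lines.append(
            f"{o.structure_id}\t{o.chain_id}\t{o.motif_name}\t"
            f"{o.binding_mode.value}\t{o.ca_distance:.4f}\t{theta}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_summary(
    summaries: dict[str, GeometrySummary], path: str | Path
) -> None:
    Path(path).write_text(
        json.dumps({k: v.to_dict() for k, v in summaries.items()}, indent=1)
    )
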