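"""Dataset assembly: annotations, binding modes, redundancy clustering.

Chains are annotated from a TSV table (aaRS class and type, organism,
mutational status, resolution), assigned a binding mode from their ligand
inventory, clustered at >95% global sequence identity with single-linkage,
and reduced to deterministic representatives.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .structure import StructureChain

# class membership of the 20+ aaRS types (by amino acid handled); lysine is
# ambivalent (Class I LysRS exists in archaea) and is listed under both.
CLASS_OF_TYPE = {
    "ArgRS": "I", "CysRS": "I", "GluRS": "I", "GlnRS": "I", "IleRS": "I",
    "LeuRS": "I", "MetRS": "I", "TrpRS": "I", "TyrRS": "I", "ValRS": "I",
    "LysRS-I": "I",
    "AlaRS": "II", "AsnRS": "II", "AspRS": "II", "GlyRS": "II", "HisRS": "II",
    "LysRS": "II", "PheRS": "II", "ProRS": "II", "SerRS": "II", "ThrRS": "II",
    "SepRS": "II", "PylRS": "II",
}


class BindingMode(str, enum.Enum):
    """M1: an adenosine-phosphate-containing ligand is bound; M2: not."""

    M1 = "M1"
    M2 = "M2"


@dataclass
class ChainAnnotation:
    structure_id: str
    chain_id: str
    aars_class: str
    aars_type: str
    superkingdom: str = ""
    taxonomy_id: int = 0
    mutant: bool = False
    resolution: float | None = None

    def __post_init__(self):
        if self.aars_class not in ("I", "II"):
            raise ValueError(f"aars_class must be I or II, got {self.aars_class!r}")
        expected = CLASS_OF_TYPE.get(self.aars_type)
        if expected is not None and expected != self.aars_class:
            raise ValueError(
                f"{self.aars_type} belongs to Class {expected}, "
                f"annotation says {self.aars_class}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.structure_id, self.chain_id)


@dataclass
class ClusterParams:
    identity_threshold: float = 95.0
    linkage: str = "single"

    def __post_init__(self):
        if not 0 < self.identity_threshold <= 100:
            raise ValueError("identity threshold must be in (0, 100]")
        if self.linkage != "single":
            raise ValueError("only single linkage is supported")


def assign_binding_mode(chain: StructureChain) -> BindingMode:
    """M1 iff any attached ligand carries the adenosine phosphate moiety."""
    if any(l.has_adenosine_phosphate for l in chain.ligands):
        return BindingMode.M1
    return BindingMode.M2


# ---------------------------------------------------------------------------
# sequence identity and clustering

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER: Align.PairwiseAligner | None = None


def global_alignment(seq_a: str, seq_b: str):
    """Best global Needleman-Wunsch alignment (BLOSUM62, gap 10/0.5)."""
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = _make_aligner()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    return _ALIGNER.align(seq_a.upper(), seq_b.upper())[0]


def _identity_from_columns(cols_a: str, cols_b: str) -> float:
    """Percent identity over aligned columns, terminal-gap overhangs excluded.

    The scored region runs from the first to the last column where both
    sequences are present; internal gaps still count in the denominator.
    """
    n = len(cols_a)
    start, end = 0, n
    while start < n and (cols_a[start] == "-" or cols_b[start] == "-"):
        start += 1
    while end > start and (cols_a[end - 1] == "-" or cols_b[end - 1] == "-"):
        end -= 1
    core_a, core_b = cols_a[start:end], cols_b[start:end]
    total = len(core_a)
    if total == 0:
        return 0.0
    same = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    return 100.0 * same / total


def global_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent identity between two protein sequences."""
    aln = global_alignment(seq_a, seq_b)
    a, b = str(aln[0]), str(aln[1])
    return _identity_from_columns(a, b)


def single_linkage_clusters(
    sequences: Sequence[str],
    params: ClusterParams | None = None,
    identity_fn: Callable[[str, str], float] = global_identity,
) -> list[list[int]]:
    """Cluster sequence indices: edges where identity > threshold, connected
    components. Every index lands in exactly one cluster; output is sorted
    for order-invariance."""
    import networkx as nx

    params = params or ClusterParams()
    g = nx.Graph()
    g.add_nodes_from(range(len(sequences)))
    cache: dict[str, float] = {}
    for i in range(len(sequences)):
        for j in range(i + 1, len(sequences)):
            key = (
                sequences[i] + "|" + sequences[j]
                if sequences[i] <= sequences[j]
                else sequences[j] + "|" + sequences[i]
            )
            ident = cache.get(key)
            if ident is None:
                ident = identity_fn(sequences[i], sequences[j])
                cache[key] = ident
            if ident > params.identity_threshold:
                g.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps)


def select_representative(
    cluster: Sequence[ChainAnnotation],
    modes: dict[tuple[str, str], BindingMode] | None = None,
    mode: str = "overall",
) -> ChainAnnotation:
    """Deterministic representative: wild type > binding-mode match (for
    ``mode`` 'M1'/'M2') > best (lowest) resolution > lexicographic id."""
    if not cluster:
        raise ValueError("cluster is empty")
    modes = modes or {}

    def sort_key(ann: ChainAnnotation):
        mode_match = 0
        if mode in ("M1", "M2"):
            mode_match = 0 if modes.get(ann.key) == BindingMode(mode) else 1
        res = ann.resolution if ann.resolution is not None else float("inf")
        return (int(ann.mutant), mode_match, res, ann.structure_id, ann.chain_id)

    return min(cluster, key=sort_key)


# ---------------------------------------------------------------------------
# annotation I/O

ANNOTATION_COLUMNS = [
    "pdb_id", "chain", "class", "type", "superkingdom", "taxid",
    "mutant", "resolution", "ligand_codes", "binding_mode",
]


def read_annotations(path: str | Path) -> list[ChainAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        out.append(
            ChainAnnotation(
                structure_id=row["pdb_id"],
                chain_id=row["chain"],
                aars_class=row["class"],
                aars_type=row["type"],
                superkingdom=row.get("superkingdom", ""),
                taxonomy_id=int(row["taxid"]) if row.get("taxid") else 0,
                mutant=str(row.get("mutant", "")).lower() in ("1", "true", "yes"),
                resolution=float(row["resolution"]) if row.get("resolution") else None,
            )
        )
    return out


def write_annotations(
    annotations: Iterable[ChainAnnotation],
    path: str | Path,
    modes: dict[tuple[str, str], BindingMode] | None = None,
    ligand_codes: dict[tuple[str, str], list[str]] | None = None,
) -> None:
    modes = modes or {}
    ligand_codes = ligand_codes or {}
    rows = []
    for a in annotations:
        rows.append(
            {
                "pdb_id": a.structure_id,
                "chain": a.chain_id,
                "class": a.aars_class,
                "type": a.aars_type,
                "superkingdom": a.superkingdom,
                "taxid": a.taxonomy_id,
                "mutant": int(a.mutant),
                "resolution": "" if a.resolution is None else a.resolution,
                "ligand_codes": ",".join(ligand_codes.get(a.key, [])),
                "binding_mode": getattr(modes.get(a.key), "value", ""),
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)
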