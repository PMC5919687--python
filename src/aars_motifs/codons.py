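"""Consensus codons and antisense (Rodin-Ohno) middle-base complementarity.

Codons are attached to renumbered MSA columns by mapping each aligned
protein row to its coding DNA sequence. Per column and codon base position,
the information content is 2 - H bits (Shannon entropy over the four
bases); the modal base is assigned when it exceeds a 1-bit threshold,
otherwise the base is written 'x'. The Rodin-Ohno hypothesis predicts that
Class I and Class II catalytic cores descend from complementary strands of
one gene, so Class II codons are paired antiparallel against Class I:
the Class II column list and each codon's bases are reversed at pairing
time, and only Watson-Crick pairs (A-T, G-C) count as matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .renumber import MsaRow

BASES = "ACGT"
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: per-base information content (bits) above which the modal base is assigned
CONSENSUS_THRESHOLD_BITS = 1.0


class CodonAssignmentError(ValueError):
    """CDS does not translate to the aligned protein row."""


@dataclass
class CodonColumn:
    msa_column: int
    codons: list[str] = field(default_factory=list)

    def __post_init__(self):
        for c in self.codons:
            if len(c) != 3 or any(b not in BASES for b in c):
                raise ValueError(f"invalid codon {c!r}")

    @property
    def occupancy(self) -> int:
        return len(self.codons)

    def add(self, codon: str) -> None:
        codon = codon.upper()
        if len(codon) != 3 or any(b not in BASES for b in codon):
            raise ValueError(f"invalid codon {codon!r}")
        self.codons.append(codon)


@dataclass(frozen=True)
class ConsensusCodon:
    msa_column: int
    bases: str  # 3 characters, each in ACGT or 'x'
    information: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.bases) != 3 or any(b not in BASES + "x" for b in self.bases):
            raise ValueError(f"invalid consensus {self.bases!r}")

    @property
    def middle(self) -> str:
        return self.bases[1]


# ---------------------------------------------------------------------------
# codon assignment

def assign_codons(
    msa_row: MsaRow, cds: str, allow_terminal_stop: bool = True
) -> dict[int, str]:
    """Map each MSA column of the row to the codon that encodes its residue.

    The CDS must translate (standard code) to the ungapped protein row;
    otherwise the sequence is rejected with a diagnosis.
    """
    protein = msa_row.ungapped
    dna = cds.strip().upper().replace("U", "T")
    if len(dna) % 3 != 0:
        raise CodonAssignmentError(
            f"{msa_row.row_id}: CDS length {len(dna)} is not a multiple of 3"
        )
    translated = str(Seq(dna).translate())
    if allow_terminal_stop and translated.endswith("*"):
        translated = translated[:-1]
        dna = dna[:-3]
    if translated != protein:
        for i, (a, b) in enumerate(zip(translated, protein)):
            if a != b:
                raise CodonAssignmentError(
                    f"{msa_row.row_id}: translation mismatch at residue "
                    f"{i + 1} ({a!r} != {b!r})"
                )
        raise CodonAssignmentError(
            f"{msa_row.row_id}: translated length {len(translated)} != "
            f"protein length {len(protein)}"
        )
    columns = msa_row.residue_columns()
    return {col: dna[3 * i: 3 * i + 3] for i, col in enumerate(columns)}


def collect_codon_columns(
    contributions: Sequence[dict[int, str]]
) -> dict[int, CodonColumn]:
    """Merge per-sequence column->codon maps into per-column codon lists."""
    columns: dict[int, CodonColumn] = {}
    for contrib in contributions:
        for col, codon in contrib.items():
            columns.setdefault(col, CodonColumn(msa_column=col)).add(codon)
    return columns


# ---------------------------------------------------------------------------
# consensus

def base_information(codons: Sequence[str], base_index: int) -> tuple[str | None, float]:
    """Modal base and information content (bits) at one codon position.

    Information content is 2 - H with H the Shannon entropy (log2) of the
    base distribution. Returns (None, info) on a modal tie.
    """
    counts = {b: 0 for b in BASES}
    for codon in codons:
        counts[codon[base_index]] += 1
    total = sum(counts.values())
    freqs = np.array([c / total for c in counts.values()])
    nz = freqs[freqs > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    info = 2.0 - entropy
    top = max(counts.values())
    winners = [b for b, c in counts.items() if c == top]
    modal = winners[0] if len(winners) == 1 else None
    return modal, info


def consensus_codon(
    column: CodonColumn, threshold_bits: float = CONSENSUS_THRESHOLD_BITS
) -> ConsensusCodon:
    """Per-base consensus: modal base where information exceeds the
    threshold, 'x' otherwise (modal ties are also 'x')."""
    if column.occupancy < 1:
        raise ValueError(f"column {column.msa_column} has no codons")
    bases = []
    infos = []
    for i in range(3):
        modal, info = base_information(column.codons, i)
        infos.append(round(info, 6))
        bases.append(modal if (modal is not None and info > threshold_bits) else "x")
    return ConsensusCodon(
        msa_column=column.msa_column, bases="".join(bases), information=tuple(infos)
    )


def build_consensus(
    columns: dict[int, CodonColumn],
    threshold_bits: float = CONSENSUS_THRESHOLD_BITS,
    min_occupancy: int = 1,
) -> list[ConsensusCodon]:
    """Consensus codons for all columns meeting the occupancy floor,
    ascending by column."""
    return [
        consensus_codon(col, threshold_bits)
        for _, col in sorted(columns.items())
        if col.occupancy >= min_occupancy
    ]


# ---------------------------------------------------------------------------
# antisense pairing

@dataclass
class PairingAssessment:
    """Columnwise verdicts for the antiparallel Class I / Class II pairing.

    ``pairs`` holds (class I column, class II column, verdict) where the
    verdict is three characters from {'.', '|', 'x'}: unassigned, match
    (Watson-Crick complementary), mismatch. Base k of the Class I codon is
    compared against base 3-k of the Class II codon (antiparallel strands).
    """

    pairs: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def middle_base_matches(self) -> int:
        return sum(1 for _, _, v in self.pairs if v[1] == "|")

    @property
    def marker_rows(self) -> list[str]:
        return [v for _, _, v in self.pairs]

    def matched_class_i_columns(self) -> list[int]:
        return [ci for ci, _, v in self.pairs if v[1] == "|"]

    def matched_pair_labels(self) -> list[str]:
        return [f"{ci}-{cii}" for ci, cii, v in self.pairs if v[1] == "|"]


def _verdict(base_i: str, base_ii: str) -> str:
    if base_i == "x" or base_ii == "x":
        return "."
    return "|" if COMPLEMENT[base_i] == base_ii else "x"


def antisense_pairing(
    class_i: Sequence[ConsensusCodon], class_ii: Sequence[ConsensusCodon]
) -> PairingAssessment:
    """Pair Class I consensus codons against reversed Class II codons.

    Both inputs are given 5'->3' in ascending column order; the Class II
    list and each Class II codon's bases are reversed here, so the first
    Class I base faces the third base of its Class II partner and middle
    faces middle.
    """
    if len(class_i) != len(class_ii):
        raise ValueError(
            f"aligned regions differ in length: {len(class_i)} vs {len(class_ii)}"
        )
    result = PairingAssessment()
    flipped = list(reversed(class_ii))
    for ci, cii in zip(class_i, flipped):
        rev = cii.bases[::-1]
        verdict = "".join(_verdict(a, b) for a, b in zip(ci.bases, rev))
        result.pairs.append((ci.msa_column, cii.msa_column, verdict))
    return result


# ---------------------------------------------------------------------------
# published reference consensus codons for the Rodin-Ohno regions
# (structure-guided MSA numbering; Class II codons stored 5'->3' ascending)

def _region(class_i_positions, class_i_codons, class_ii_positions_printed,
            class_ii_codons_printed):
    """Printed tables list Class II in pairing orientation (descending
    positions, bases already reversed); store them 5'->3' ascending."""
    class_i = [
        ConsensusCodon(msa_column=p, bases=c)
        for p, c in zip(class_i_positions, class_i_codons)
    ]
    class_ii = [
        ConsensusCodon(msa_column=p, bases=c[::-1])
        for p, c in sorted(
            zip(class_ii_positions_printed, class_ii_codons_printed)
        )
    ]
    return class_i, class_ii


HIGH_MOTIF2_REFERENCE = _region(
    class_i_positions=list(range(272, 286)),
    class_i_codons=[
        "xxx", "xxx", "xAx", "xCx", "Axx", "Gxx", "xxx", "xxx", "xTx",
        "CAx", "xTx", "GGx", "xAx", "xxx",
    ],
    class_ii_positions_printed=list(range(701, 687, -1)),
    class_ii_codons_printed=[
        "xxx", "GAx", "xAx", "xGx", "TTx", "xxx", "xxx", "xxx", "xxx",
        "xTx", "xxx", "xxx", "xTx", "xxx",
    ],
)

KMSKS_MOTIF1_REFERENCE = _region(
    class_i_positions=[1352, 1356, 1360, 1361, 1414, 1415, 1416, 1417,
                       1418, 1444, 1450, 1452],
    class_i_codons=[
        "xxx", "xxx", "xxx", "xTx", "AAx", "xTx", "xxx", "Axx", "xxx",
        "xxx", "xxx", "xxx",
    ],
    class_ii_positions_printed=[371, 370, 368, 366, 365, 364, 363, 362,
                                361, 352, 348, 347],
    class_ii_codons_printed=[
        "xxx", "CCx", "xxx", "xxx", "xTx", "xxx", "xxx", "xxx", "GGx",
        "xxx", "xxx", "xxx",
    ],
)

REFERENCE_REGIONS = {
    "HIGH-Motif2": HIGH_MOTIF2_REFERENCE,
    "KMSKS-Motif1": KMSKS_MOTIF1_REFERENCE,
}


# ---------------------------------------------------------------------------
# report writers

def write_consensus_tsv(consensus: Sequence[ConsensusCodon], path: str | Path) -> None:
    lines = ["msa_column\tconsensus\tinfo_base1\tinfo_base2\tinfo_base3"]
    for c in consensus:
        i1, i2, i3 = c.information
        lines.append(f"{c.msa_column}\t{c.bases}\t{i1:.4f}\t{i2:.4f}\t{i3:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def format_pairing_table(
    class_i: Sequence[ConsensusCodon],
    class_ii: Sequence[ConsensusCodon],
    assessment: PairingAssessment | None = None,
) -> str:
    """Plain-text pairing table: Class I row, marker row, Class II row
    (printed in pairing orientation)."""
    if assessment is None:
        assessment = antisense_pairing(class_i, class_ii)
    flipped = list(reversed(class_ii))
    rows = [
        "C I \t" + "\t".join(str(c.msa_column) for c in class_i),
        "    \t" + "\t".join(c.bases for c in class_i),
        "    \t" + "\t".join(v for _, _, v in assessment.pairs),
        "C II\t" + "\t".join(c.bases[::-1] for c in flipped),
        "    \t" + "\t".join(str(c.msa_column) for c in flipped),
    ]
    return "\n".join(rows) + "\n"
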