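# Methods

## Scope and model

The package analyses the ATP-recognition core of aminoacyl-tRNA
synthetases (aaRS). Both enzyme classes must bind the adenosine phosphate
moiety of ATP / aminoacyl-adenylate, and they do so with class-specific
two-residue motifs expressed in a *unified residue coordinate system*: the
column index of a class-specific structure-guided multiple sequence
alignment. In that coordinate system the Class I motif (Backbone Brackets)
sits at columns 274/1361 and the Class II motif (Arginine Tweezers) at
698/1786. All downstream statements — interaction preferences, geometry
distributions, codon-level complementarity — are made in these renumbered
positions, which is what makes chains from different organisms and aaRS
types comparable.

The pipeline has five stages. Each stage persists plain-text artifacts
(TSV/JSON/PDB/FASTA) and later stages consume them, so partial runs are
possible and every intermediate is inspectable.

## Dataset stage

A chain enters the dataset with annotations (aaRS class and type,
superkingdom, taxon, mutational status, resolution) read from a TSV table.
Binding mode is a function of the ligand inventory: **M1** iff at least one
attached ligand contains an adenosine-phosphate substructure, **M2**
otherwise (apo chains and chains carrying only a free amino acid are M2).
Ligand flags come from a curated component table first, and otherwise from
the inferred bond graph (bond iff interatomic distance < sum of covalent
radii + 0.4 Å): an adenosine phosphate requires a fused 6–5 aromatic
N-heterocycle with ≥ 4 nitrogens, glycosidically bonded to a 5-ring with
one ring oxygen, and a phosphate ester reachable from that ring; an
aminoacyl part requires a free α-amino-acid fragment (N–Cα–carbonyl)
outside the nucleotide. An aminoacyl-adenylate therefore sets both flags.

Redundancy is removed by single-linkage clustering at > 95 % global
identity. Identity uses Needleman–Wunsch with BLOSUM62 and gap open/extend
10/0.5 (classic `needle` defaults, since only the algorithm is specified by
the source analysis), with terminal-gap overhangs excluded from the
denominator so that expression tags do not dominate the 95 % criterion.
Representatives are selected deterministically per cluster: wild type
first, then (for the M1/M2 representatives) binding-mode match, then best
resolution, then lexicographic identifier. This priority order is a
reconstruction — the original selection scheme is not published in the main
text — and is isolated in one function should it need revision.

Ligand-to-chain attribution (unstated in the source analysis) uses a
majority rule: a HETATM group belongs to the chain contributing the most
polymer atoms within 4.0 Å of any ligand atom, ties toward the lower chain
identifier; groups touching no chain are dropped with a log entry. Only
model 1 of multi-model files is read, and the highest-occupancy altloc
conformer is kept (ties toward 'A').

## Renumbering stage

A chain is mapped to the MSA row maximising global identity, then aligned
to that row's ungapped sequence; composition with the row's gap pattern
yields an injective, strictly increasing map from author numbering to
1-based MSA columns. Chains whose best row falls below 40 % identity are
refused and listed in a failure file — the threshold is this package's
choice; the source analysis lists failures without a criterion. Renumbered
structures keep ligand numbering untouched; polymer residues outside the
map keep their original numbers (they are reported in the map's unmapped
list rather than dropped, so renumbering is reversible).

## Interaction profiling

Crystal structures rarely include hydrogens, so donor/acceptor capacity is
inferred from heavy atoms: backbone N donates (except proline), backbone O
accepts, side chains follow a chemistry table, and ligand N/O atoms may do
either. Rules and defaults (all configurable):

| kind          | rule                                                              |
|---------------|-------------------------------------------------------------------|
| hydrogen bond | donor–acceptor ≤ 4.1 Å and bonded-neighbour–donor–acceptor ≥ 100° |
| salt bridge   | charged-group centroids ≤ 5.5 Å (Arg/Lys/His⁺ vs phosphate or carboxylate; Asp/Glu vs ligand amine) |
| π-cation      | cation (centroid) to aromatic ring centroid ≤ 6.0 Å               |
| π-stacking    | ring centroids ≤ 5.5 Å, plane angle < 30° or 60–90°               |
| hydrophobic   | apolar C – apolar C ≤ 4.0 Å, one record per residue and fragment  |
| metal complex | metal ion ≤ 3.0 Å from a ligand atom                              |

Every ligand atom receives exactly one fragment label: phosphate (P and its
bonded O), adenine (fused-ring atoms plus exocyclic N/O), ribose (furanose
ring, exocyclic O, and ring-attached carbons such as C5′), remainder
aminoacyl. The per-type preference matrix counts, per (aaRS type,
renumbered position, fragment) cell, in how many representative M1
complexes each interaction kind occurs — at most once per complex, so a
hydrogen bond with three donor atoms does not outvote a single salt bridge
— plus a no-contact tally for complexes that expose the position without
contacting the fragment. Positions relevant to fewer than two aaRS types
are discarded; ties are reported as dual preferences (at most two).

## Geometry

A motif occurrence yields two descriptors: the Cα–Cα distance, and the
side-chain angle θ between the two vectors from each Cα to its most
distant side-chain carbon atom (Euclidean distance in the deposited
conformation, not bond topology; ties break toward the lexicographically
smallest atom name for determinism). θ is undefined for glycine or when no
side-chain carbon is resolved; undefined angles are excluded listwise from
θ statistics while their distances are kept, because the two descriptors
are analysed independently. M1 and M2 groups are summarised (mean, sample
SD) and compared with a two-sided Mann–Whitney U test — exact enumeration
for tie-free groups of ≤ 20, tie-corrected normal approximation otherwise
(the sidedness is this package's choice; the source reports only p<0.01).
Motif backbones (N, CA, C, O of both residues) are superposed pairwise
with a least-squares Kabsch fit; the all-vs-all mean RMSD is reported.

## Codon analysis

Coding sequences are validated by translation against the ungapped protein
row (terminal stop allowed; any mismatch rejects the sequence with a
diagnosis) and each residue's codon is attached to its MSA column. Per
codon base position the information content is 2 − H bits (Shannon entropy
over A/C/G/T); the modal base is assigned when the information content
exceeds 1 bit, `x` otherwise (modal ties are `x`). The published phrase
"entropy higher than one bit" is interpreted as information content > 1 bit
— the literal reading (assigning bases at *high* entropy) would contradict
the published conserved-middle-base tables.

Antisense pairing follows the Rodin–Ohno antiparallel-strand picture:
Class II consensus codons are stored 5′→3′ and, at pairing time, the
column list and each codon's bases are reversed so that Class I base 1
faces Class II base 3 and middle faces middle. Only A–T and G–C count as
matches (no wobble). The published tables print Class II codons already in
pairing orientation; the packaged reference constants store them 5′→3′ so
the same pairing routine reproduces the printed marker rows. Because the
published prose labels the conserved pairs by a convention that is offset
by one from the printed column alignment (e.g. "274-698" where the table's
markers support 275–698), reports are emitted both by Class I column and by
pair label.

## Synthetic data generator

The generator emulates exactly the features the pipeline measures, with
ground truth recorded per chain:

* **Geometry.** The two motif residues are built in a canonical frame (one
  Cα at the origin, the other at the planted distance along x; the most
  distant side-chain carbon placed exactly along the planted direction), so
  planted distance and θ are exact to machine precision. Default planted
  distributions are the study conditions — Class I: 17.92 ± 0.86 Å (M1),
  18.41 ± 0.82 Å (M2), θ 144.90 ± 20.93° / 141.40 ± 20.13°; Class II:
  14.76 ± 0.66 / 14.93 ± 0.79 Å, θ 91.82 ± 8.69° / 79.81 ± 21.67°. Draws
  are truncated at ±3 SD and at the valid angle range (0–180°); recovery is
  always checked against the realised draws, which the truth table records.
* **Ligand.** An idealised AMP built from regular-polygon geometry (hexagon
  side 1.39 Å fused to a pentagon, furanose side 1.43 Å, phosphate arm)
  that satisfies the same bond-graph detection rules as real nucleotides.
  For M1 chains the ligand is posed between the motif residues by a small
  deterministic grid search (axis offset × lift × roll) accepted only when
  *exactly* the planted interaction inventory fires — backbone hydrogen
  bonds at 274/1361 for Class I; salt bridge + π-cation (plus the
  unavoidable accompanying side-chain hydrogen bonds) at 698/1786 for
  Class II. Infeasible geometry raises a generation error.
* **Isolation.** Filler residues sit on a rail ≥ 10 Å from the ligand so no
  unplanned contacts arise. Chains are written as standard PDB files;
  nothing downstream distinguishes them from parsed crystal structures.
* **Sequences and codons.** Each chain's MSA row places its residues at
  fixed columns (motifs at the canonical positions); coding sequences plant
  conserved complementary middle bases at three designated column pairs
  (275–698 Pro/Arg, 281–692 Gln/Leu, 284–689 Lys/Met) and scramble middle
  bases elsewhere, so the expected pairing count is 3 by construction.

What the generator does **not** emulate: real backbone connectivity and
sterics, crystallographic noise and disorder (optional Gaussian jitter
exists but defaults to 0 and voids the interaction guarantee), sequence
divergence beyond a few variable columns, alternative ligand chemistries,
and the MSA ambiguity of genuinely divergent chains. Passing the synthetic
closed loops therefore demonstrates the correctness of the pipeline's
bookkeeping and geometry, not the robustness of the geometric rules on
noisy experimental data — the latter is covered by the download-gated
checks against real PDB entries.

Cohort size defaults to 100 chains per class (200 total, the size used in
the property-based acceptance checks), balanced M1/M2 (the published
analysis implies roughly balanced representative sets but states no
fraction), all chains mapping, no glycine substitutions; tests vary these
explicitly.

## Numerical choices

* Bond inference slack 0.4 Å over covalent radii (common heuristic for HET
  groups without connectivity records).
* PDB coordinates round-trip at the format's 3-decimal precision; geometry
  asserted through file I/O uses tolerances ≥ 1e-3 Å accordingly, direct
  in-memory geometry 1e-6 or tighter.
* Mann–Whitney switches to the asymptotic tie-corrected form when ties are
  present or a group exceeds 20.
* Kabsch superposition uses SVD with a determinant correction for
  reflections; the test suite cross-checks against an independent
  quaternion (Horn) implementation.
* All randomness flows through seeded `numpy` generators; per-chain
  substreams are derived from (cohort seed, chain index) so chains are
  independent of cohort size.

## Known limitations

* The representative-selection priority and the 40 % mapping-refusal
  threshold are reconstructions; on the real corpus they can shift which
  chains enter the M1/M2 representative sets by a few entries.
* Interaction profiling without hydrogens over-detects donors/acceptors in
  chemically ambiguous ligands; cutoffs are configurable but defaults are
  deliberately conventional.
* Chains absent from the MSA are mapped through their best-identity row;
  for genuinely ambivalent alignment regions the mapping is reported, not
  disambiguated.
* mmCIF input is accepted through the same parser entry point, but the
  fixed-width PDB dialect is the reference format and the only one written.
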