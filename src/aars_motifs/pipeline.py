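"""Pipeline orchestration and report writers.

Stages mirror the analysis workflow: ``dataset`` (parse structures, assign
binding modes, cluster, pick representatives), ``renumber`` (MSA mapping,
renumbered structures, mapping tables), ``interactions`` (profiling of M1
representatives and the per-type preference matrix), ``geometry`` (motif
descriptors and the M1-vs-M2 comparison), ``codons`` (consensus codons and
the antisense pairing). Each stage persists its artifacts under the output
directory and later stages read them back, so stages can be run
separately; a missing prerequisite raises a named error. A machine-readable
manifest records per-stage counts and a configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import codons as codon_mod
from .dataset import (
    BindingMode,
    ChainAnnotation,
    ClusterParams,
    assign_binding_mode,
    read_annotations,
    select_representative,
    single_linkage_clusters,
)
from .geometry import (
    GeometrySummary,
    MotifObservation,
    observe_motif,
    summarize_geometry,
    write_observations,
    write_summary,
)
from .interactions import (
    InteractionConfig,
    annotate_interactions,
    build_interaction_matrix,
    write_interaction_records,
)
from .renumber import (
    MOTIF_OF_CLASS,
    MappingError,
    build_renumber_map,
    locate_motif,
    read_msa,
    renumber_chain,
    write_mapping_table,
)
from .structure import StructureChain, chain_sequence, parse_structure, write_pdb

logger = logging.getLogger(__name__)

STAGES = ("dataset", "renumber", "interactions", "geometry", "codons")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class CohortConfig:
    aars_class: str
    structures_dir: str
    annotations: str
    msa: str
    cds: str | None = None


@dataclass
class PipelineConfig:
    cohorts: list[CohortConfig]
    output_dir: str
    identity_threshold: float = 95.0
    mapping_threshold: float = 40.0
    consensus_bits: float = 1.0
    geometry_scope: str = "representatives"  # or "all"
    interaction: InteractionConfig = field(default_factory=InteractionConfig)
    #: equal-length renumbered-column intervals paired antiparallel
    pairing_regions: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cohorts = [CohortConfig(**c) for c in raw.pop("cohorts")]
        inter = raw.pop("interaction", None)
        cfg = cls(cohorts=cohorts, **raw)
        if inter:
            cfg.interaction = InteractionConfig(**inter)
        return cfg

    def config_hash(self) -> str:
        def enc(o):
            if hasattr(o, "__dict__"):
                return vars(o)
            return str(o)

        blob = json.dumps(vars(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------

def _load_cohort_chains(cohort: CohortConfig) -> dict[tuple[str, str], StructureChain]:
    chains: dict[tuple[str, str], StructureChain] = {}
    for path in sorted(Path(cohort.structures_dir).glob("*.pdb")):
        for chain in parse_structure(path):
            chains[(chain.structure_id, chain.chain_id)] = chain
    return chains


def _dataset_table_path(out: Path, aars_class: str) -> Path:
    return out / f"dataset_class{aars_class}.tsv"


def run_dataset_stage(config: PipelineConfig, cohort: CohortConfig, out: Path) -> dict:
    chains = _load_cohort_chains(cohort)
    annotations = read_annotations(cohort.annotations)
    annotations = [a for a in annotations if a.key in chains]
    if not annotations:
        raise PipelineError("dataset", f"no annotated chains found for class {cohort.aars_class}")

    modes = {a.key: assign_binding_mode(chains[a.key]) for a in annotations}
    seqs = [chain_sequence(chains[a.key], mode="parent") for a in annotations]
    clusters = single_linkage_clusters(
        seqs, ClusterParams(identity_threshold=config.identity_threshold)
    )
    rows = []
    for cluster_id, members in enumerate(clusters):
        anns = [annotations[i] for i in members]
        rep = {
            kind: select_representative(anns, modes=modes, mode=kind).key
            for kind in ("overall", "M1", "M2")
        }
        for i in members:
            a = annotations[i]
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
                    "ligand_codes": ",".join(
                        l.component_code for l in chains[a.key].ligands
                    ),
                    "binding_mode": modes[a.key].value,
                    "cluster_id": cluster_id,
                    "rep_overall": int(a.key == rep["overall"]),
                    "rep_M1": int(a.key == rep["M1"]),
                    "rep_M2": int(a.key == rep["M2"]),
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(_dataset_table_path(out, cohort.aars_class), sep="\t", index=False)
    return {
        "chains": len(annotations),
        "clusters": len(clusters),
        "M1": sum(m == BindingMode.M1 for m in modes.values()),
        "M2": sum(m == BindingMode.M2 for m in modes.values()),
    }


def _read_dataset_table(out: Path, aars_class: str, stage: str) -> pd.DataFrame:
    path = _dataset_table_path(out, aars_class)
    if not path.exists():
        raise PipelineError(stage, f"missing dataset table {path}; run the dataset stage first")
    return pd.read_csv(path, sep="\t")


def run_renumber_stage(config: PipelineConfig, cohort: CohortConfig, out: Path) -> dict:
    _read_dataset_table(out, cohort.aars_class, "renumber")
    chains = _load_cohort_chains(cohort)
    msa = read_msa(cohort.msa)
    renum_dir = out / f"renumbered_class{cohort.aars_class}"
    renum_dir.mkdir(exist_ok=True)
    maps = {}
    failures = []
    for key in sorted(chains):
        chain = chains[key]
        try:
            mapping = build_renumber_map(
                chain, msa, identity_threshold=config.mapping_threshold
            )
        except (MappingError, ValueError) as exc:
            failures.append(f"{key[0]}_{key[1]}\t{exc}")
            logger.warning("renumbering failed for %s_%s: %s", key[0], key[1], exc)
            continue
        maps[key] = mapping
        renumbered = renumber_chain(chain, mapping)
        write_pdb([renumbered], renum_dir / f"{key[0]}_{key[1]}.pdb")
    write_mapping_table(maps, out / f"mapping_class{cohort.aars_class}.tsv")
    (out / f"mapping_failed_class{cohort.aars_class}.txt").write_text(
        "\n".join(failures) + ("\n" if failures else "")
    )
    return {"chains": len(chains), "mapped": len(maps), "failed": len(failures)}


def _load_renumbered(out: Path, aars_class: str, stage: str) -> dict:
    renum_dir = out / f"renumbered_class{aars_class}"
    if not renum_dir.exists():
        raise PipelineError(stage, f"missing {renum_dir}; run the renumber stage first")
    chains = {}
    for path in sorted(renum_dir.glob("*.pdb")):
        sid, chain_id = path.stem.rsplit("_", 1)
        for chain in parse_structure(path):
            chains[(sid, chain_id)] = chain
    return chains


def run_interactions_stage(config: PipelineConfig, cohort: CohortConfig, out: Path) -> dict:
    df = _read_dataset_table(out, cohort.aars_class, "interactions")
    chains = _load_renumbered(out, cohort.aars_class, "interactions")
    all_records = []
    annotated = []
    reps = df[(df["rep_M1"] == 1) & (df["binding_mode"] == "M1")]
    for _, row in reps.iterrows():
        key = (str(row["pdb_id"]), str(row["chain"]))
        chain = chains.get(key)
        if chain is None:
            continue
        ligand = next(
            (l for l in chain.ligands if l.has_adenosine_phosphate), None
        )
        if ligand is None:
            continue
        records = annotate_interactions(chain, ligand, config.interaction)
        present = {r.author_number for r in chain.polymer_residues}
        annotated.append((str(row["type"]), records, present))
        all_records.extend((key[0], key[1], r) for r in records)
    matrix = build_interaction_matrix(annotated)
    write_interaction_records(
        all_records, out / f"interactions_class{cohort.aars_class}.tsv"
    )
    matrix.write_tsv(out / f"interaction_matrix_class{cohort.aars_class}.tsv")
    matrix.write_json(out / f"interaction_matrix_class{cohort.aars_class}.json")
    return {
        "complexes": len(annotated),
        "records": len(all_records),
        "matrix_cells": len(matrix.cells),
    }


def run_geometry_stage(config: PipelineConfig, cohort: CohortConfig, out: Path) -> dict:
    df = _read_dataset_table(out, cohort.aars_class, "geometry")
    chains = _load_renumbered(out, cohort.aars_class, "geometry")
    motif = MOTIF_OF_CLASS[cohort.aars_class]
    observations: list[MotifObservation] = []
    not_mapped = 0
    for _, row in df.iterrows():
        mode = BindingMode(row["binding_mode"])
        if config.geometry_scope == "representatives":
            rep_col = "rep_M1" if mode == BindingMode.M1 else "rep_M2"
            if int(row[rep_col]) != 1:
                continue
        key = (str(row["pdb_id"]), str(row["chain"]))
        chain = chains.get(key)
        if chain is None:
            continue
        hit = locate_motif(chain, motif)
        if not hit.mapped:
            not_mapped += 1
            logger.warning(
                "motif not mapped for %s_%s (missing %s)", key[0], key[1], hit.missing
            )
            continue
        observations.append(
            observe_motif(
                key[0], key[1], motif.name, motif.positions,
                hit.residues[0], hit.residues[1], mode,
            )
        )
    summary = summarize_geometry(observations)
    write_observations(
        observations, out / f"geometry_observations_class{cohort.aars_class}.tsv"
    )
    write_summary(
        {motif.name: summary}, out / f"geometry_summary_class{cohort.aars_class}.json"
    )
    theta_defined = sum(1 for o in observations if o.theta is not None)
    return {
        "observations": len(observations),
        "not_mapped": not_mapped,
        "theta_defined": theta_defined,
        "theta_undefined": len(observations) - theta_defined,
    }


def run_codons_stage(config: PipelineConfig, out: Path) -> dict:
    consensus_by_class: dict[str, dict[int, codon_mod.ConsensusCodon]] = {}
    counts = {}
    for cohort in config.cohorts:
        if cohort.cds is None:
            continue
        msa = read_msa(cohort.msa)
        from Bio import SeqIO

        cds = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(cohort.cds, "fasta")
        }
        contributions = []
        rejected = 0
        for row in msa:
            seq = cds.get(row.row_id)
            if seq is None:
                continue
            try:
                contributions.append(codon_mod.assign_codons(row, seq))
            except codon_mod.CodonAssignmentError as exc:
                rejected += 1
                logger.warning("%s", exc)
        columns = codon_mod.collect_codon_columns(contributions)
        consensus = codon_mod.build_consensus(columns, config.consensus_bits)
        consensus_by_class[cohort.aars_class] = {c.msa_column: c for c in consensus}
        codon_mod.write_consensus_tsv(
            consensus, out / f"consensus_class{cohort.aars_class}.tsv"
        )
        counts[f"class{cohort.aars_class}_columns"] = len(consensus)
        counts[f"class{cohort.aars_class}_rejected"] = rejected

    regions = config.pairing_regions
    if regions and {"I", "II"} <= set(consensus_by_class):
        lo_i, hi_i = regions["class_i"]
        lo_ii, hi_ii = regions["class_ii"]
        ci = [
            consensus_by_class["I"].get(c, codon_mod.ConsensusCodon(c, "xxx"))
            for c in range(lo_i, hi_i + 1)
        ]
        cii = [
            consensus_by_class["II"].get(c, codon_mod.ConsensusCodon(c, "xxx"))
            for c in range(lo_ii, hi_ii + 1)
        ]
        assessment = codon_mod.antisense_pairing(ci, cii)
        (out / "pairing.txt").write_text(
            codon_mod.format_pairing_table(ci, cii, assessment)
        )
        pd.DataFrame(
            [
                {"class_i_column": a, "class_ii_column": b, "verdict": v}
                for a, b, v in assessment.pairs
            ]
        ).to_csv(out / "pairing.tsv", sep="\t", index=False)
        counts["middle_base_matches"] = assessment.middle_base_matches
    return counts


def run_pipeline(config: PipelineConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the requested stages (all by default) and write the manifest."""
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "stages": {}}
    for stage in STAGES:
        if stage not in stages:
            continue
        if stage == "codons":
            manifest["stages"]["codons"] = run_codons_stage(config, out)
            continue
        per_class = {}
        for cohort in config.cohorts:
            runner = {
                "dataset": run_dataset_stage,
                "renumber": run_renumber_stage,
                "interactions": run_interactions_stage,
                "geometry": run_geometry_stage,
            }[stage]
            per_class[cohort.aars_class] = runner(config, cohort, out)
        manifest["stages"][stage] = per_class
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# sequence-logo-style frequency tables

def sequence_logo_table(
    chains: Sequence[StructureChain], position: int, window: int = 3
) -> pd.DataFrame:
    """Residue frequencies per renumbered column around ``position``.

    Rows are columns position-window .. position+window, columns are
    one-letter residue codes; values are relative frequencies over the
    chains that expose the column. Suitable for external logo rendering.
    """
    from .structure import THREE_TO_ONE

    records = {}
    for col in range(position - window, position + window + 1):
        counts: dict[str, int] = {}
        for chain in chains:
            res = chain.residue_at(col)
            if res is None or not res.is_polymer:
                continue
            letter = THREE_TO_ONE.get(res.name.upper(), "X")
            counts[letter] = counts.get(letter, 0) + 1
        total = sum(counts.values())
        records[col] = (
            {aa: n / total for aa, n in sorted(counts.items())} if total else {}
        )
    return pd.DataFrame.from_dict(records, orient="index").fillna(0.0)
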