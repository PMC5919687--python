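from __future__ import annotations

import pytest

from aars_motifs.pipeline import CohortConfig, PipelineConfig, run_pipeline
from aars_motifs.synthetic import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def paired_cohort(tmp_path_factory):
    """A small two-class synthetic cohort with ground truth, plus a pipeline
    configuration pointing at it (shared across the suite)."""
    root = tmp_path_factory.mktemp("cohort")
    truths, cohorts = {}, []
    for aars_class in ("I", "II"):
        spec = SyntheticSpec(
            aars_class=aars_class, seed=11, n_chains=14,
            glycine_fraction=0.3 if aars_class == "I" else 0.0,
            motif_present_fraction=0.9,
        )
        sub = root / f"class{aars_class}"
        truths[aars_class] = generate_cohort(spec, sub)
        cohorts.append(
            CohortConfig(
                aars_class=aars_class,
                structures_dir=str(sub / "structures"),
                annotations=str(sub / "annotations.tsv"),
                msa=str(sub / "msa.fasta"),
                cds=str(sub / "cds.fasta"),
            )
        )
    config = PipelineConfig(
        cohorts=cohorts,
        output_dir=str(root / "results"),
        geometry_scope="all",
        pairing_regions={"class_i": [272, 285], "class_ii": [688, 701]},
    )
    return {"root": root, "truths": truths, "config": config}


@pytest.fixture(scope="session")
def pipeline_results(paired_cohort):
    manifest = run_pipeline(paired_cohort["config"])
    return {**paired_cohort, "manifest": manifest}
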