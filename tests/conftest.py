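import numpy as np
import pandas as pd
import pytest

import metasputum as ms


@pytest.fixture(scope="session")
def design():
    """Small two-group design with planted fold-4 genera and 2 contaminants."""
    return ms.make_design(
        n_taxa=20,
        n_contaminants=2,
        effect_size=4.0,
        seed=11,
        reads_per_sample=2000,
        overdispersion=0.01,
    )


@pytest.fixture(scope="session")
def cohort_bundle(design, tmp_path_factory):
    """Simulated cohort with corruption and multi-hit reads, written to disk."""
    outdir = tmp_path_factory.mktemp("cohort")
    return ms.generate_cohort(design, outdir, corruption=0.2, multihit_fraction=0.05)


@pytest.fixture(scope="session")
def clean_bundle(design, tmp_path_factory):
    """Corruption-free cohort for exact truth-recovery checks."""
    outdir = tmp_path_factory.mktemp("clean_cohort")
    return ms.generate_cohort(design, outdir, corruption=0.0)


@pytest.fixture(scope="session")
def patient_assignments(cohort_bundle):
    """Similarity-filtered best-hit assignments for the patient samples."""
    out = {}
    for sample, path in cohort_bundle.assignment_paths.items():
        if sample.startswith("control"):
            continue
        df = ms.read_assignments(path)
        out[sample] = ms.best_hit_per_read(ms.filter_by_similarity(df, 90.0))
    return out


@pytest.fixture(scope="session")
def patient_groups(cohort_bundle):
    groups = cohort_bundle.groups
    return groups[groups != "control"]


@pytest.fixture(scope="session")
def genus_table(patient_assignments, patient_groups):
    return ms.aggregate_by_rank(patient_assignments, "genus", groups=patient_groups)
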