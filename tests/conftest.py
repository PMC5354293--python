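import numpy as np
import pandas as pd
import pytest

from cohortgwas import simcohort as sc
from cohortgwas.gio import CohortDataset


@pytest.fixture(scope="session")
def small_panel():
    """100 haplotypes x 400 densely spaced markers (array-like LD)."""
    return sc.generate_reference_panel(n_hap=100, n_markers=400, seed=11)


@pytest.fixture(scope="session")
def sparse_panel():
    """200 haplotypes x 2,000 sparsely spaced markers (~300 kb gaps) on 22
    chromosomes: genome-wide structure appropriate for relatedness work."""
    return sc.generate_reference_panel(n_hap=200, n_markers=2000, seed=17,
                                       mean_gap_bp=3.0e5, n_chromosomes=22)


@pytest.fixture(scope="session")
def small_study(small_panel):
    design = sc.StudyDesign("S1", "CohortA", "t2d", "HumanHap",
                            n_cases=20, n_controls=20, missing_rate=0.01)
    return sc.sample_cohort(small_panel, design, seed=23)


@pytest.fixture()
def tiny_dataset():
    """Hand-built 4-sample x 3-marker dataset for format tests."""
    geno = np.array([[0, 1, 2],
                     [1, -1, 0],
                     [2, 2, 1],
                     [0, 0, -1]], dtype=np.int8)
    markers = pd.DataFrame({
        "marker_id": ["rs1", "rs2", "rs3"],
        "chrom": ["1", "1", "2"],
        "pos": [100, 250, 90],
        "ref": ["A", "C", "G"],
        "alt": ["G", "T", "A"],
    })
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(4)]})
    return CohortDataset(geno, markers, samples, platform="HumanHap",
                         study_id="S1")
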