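import numpy as np
import pytest

from pairsplice import StudyDesign, TranscriptCountMatrix


@pytest.fixture
def tiny_tcm() -> TranscriptCountMatrix:
    """3 transcripts (2 genes) x 4 samples with hand-written counts."""
    counts = np.array([
        [10, 12, 30, 28],
        [20, 22, 18, 21],
        [5, 7, 6, 4],
    ])
    return TranscriptCountMatrix(
        counts=counts,
        transcript_ids=("tA1", "tA2", "tB1"),
        sample_ids=("s1", "s2", "s3", "s4"),
        gene_of={"tA1": "geneA", "tA2": "geneA", "tB1": "geneB"},
    )


@pytest.fixture
def design_2x2() -> StudyDesign:
    return StudyDesign(
        sample_ids=("s1", "s2", "s3", "s4"),
        condition=("ctrl", "ctrl", "treat", "treat"),
        baseline="ctrl",
        case="treat",
    )


def two_group_design(n_per_group: int) -> StudyDesign:
    n = 2 * n_per_group
    return StudyDesign(
        sample_ids=tuple(f"s{i}" for i in range(n)),
        condition=tuple(["base"] * n_per_group + ["case"] * n_per_group),
        baseline="base",
        case="case",
    )


@pytest.fixture
def design_6v6() -> StudyDesign:
    return two_group_design(6)
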