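import numpy as np
import pandas as pd
import pytest

from pankit.matrix_io import OrthologMatrix


@pytest.fixture
def toy_matrix() -> OrthologMatrix:
    """A = {g1, g2}, B = {g2, g3}, C = {g2}."""
    return OrthologMatrix(
        ["A", "B", "C"],
        ["g1", "g2", "g3"],
        np.array([[1, 1, 0], [0, 1, 1], [0, 1, 0]]),
    )


@pytest.fixture
def abc_matrix() -> OrthologMatrix:
    """A = {g1, g2}, B = {g1, g3}, C = {g3} (used by core-addition oracles)."""
    return OrthologMatrix(
        ["A", "B", "C"],
        ["g1", "g2", "g3"],
        np.array([[1, 1, 0], [1, 0, 1], [0, 0, 1]]),
    )


@pytest.fixture
def groups_file(tmp_path):
    """Hand-written 4-group / 3-strain groups file plus its expected matrix."""
    path = tmp_path / "groups.txt"
    path.write_text(
        "G1: A|x A|y B|z\n"
        "G2: A|p B|q C|r\n"
        "G3: C|solo\n"
        "G4: B|m C|n\n"
    )
    expected = pd.DataFrame(
        [[2, 1, 0, 0], [1, 1, 0, 1], [0, 1, 1, 1]],
        index=["A", "B", "C"],
        columns=["G1", "G2", "G3", "G4"],
    )
    return path, expected


@pytest.fixture
def annotations_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": ["a", "b", "c", "d", "e"],
            "strain": ["R"] * 5,
            "contig": ["c1"] * 5,
            "start": [1000, 5000, 50_000, 100_000, 100_500],
            "end": [2000, 7500, 51_000, 100_899, 101_699],
            "strand": ["+"] * 5,
            "functional_class": [""] * 5,
            "gh_family": [""] * 5,
            "has_gaps": [False] * 5,
        }
    )
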