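"""Shared fixtures: small in-memory studies and on-disk TSV fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from transwitch.expression_io import ExpressionStudy, SampleContrast

TOY_SAMPLES = ["A_TL_r1", "A_TL_r2", "A_TL_r3", "B_TL_r1", "B_TL_r2", "B_TL_r3"]

# 5-gene, 3v3 translatome toy matrix; values chosen to exercise both signs
TOY_MATRIX = np.array(
    [
        [2.10, 2.00, 2.05, 2.90, 2.95, 3.00],
        [3.00, 3.10, 3.05, 3.02, 3.08, 3.01],
        [1.50, 1.55, 1.45, 1.00, 0.95, 1.05],
        [2.50, 2.45, 2.55, 2.52, 2.48, 2.50],
        [3.50, 3.55, 3.45, 3.20, 3.25, 3.15],
    ]
)


def make_study(
    matrix: np.ndarray,
    samples: list[str] | None = None,
    detection: np.ndarray | None = None,
) -> ExpressionStudy:
    samples = samples or TOY_SAMPLES
    genes = pd.Index([f"g{i + 1}" for i in range(matrix.shape[0])], name="gene")
    li = pd.DataFrame(matrix, index=genes, columns=samples)
    dp = pd.DataFrame(
        detection if detection is not None else np.full(matrix.shape, 0.001),
        index=genes,
        columns=samples,
    )
    rows = []
    for s in samples:
        group, comp, rep = s.split("_")
        rows.append({"sample": s, "group": group, "compartment": comp,
                     "replicate": int(rep[1:])})
    meta = pd.DataFrame(rows).set_index("sample")
    return ExpressionStudy(li, dp, meta)


@pytest.fixture
def toy_study() -> ExpressionStudy:
    return make_study(TOY_MATRIX)


@pytest.fixture
def toy_contrast() -> SampleContrast:
    return SampleContrast("B", "A", "TL")


@pytest.fixture
def study_files(tmp_path, toy_study):
    """The toy study written to TSV files, for I/O round-trips and the CLI."""
    from transwitch.expression_io import write_study

    paths = (
        tmp_path / "matrix.tsv",
        tmp_path / "detection.tsv",
        tmp_path / "samples.tsv",
    )
    write_study(toy_study, *paths)
    return paths
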