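import numpy as np
import pytest

from grncop2 import ExpressionDataset, InferenceParams, generate


@pytest.fixture
def tiny_dataset():
    """3 genes x 6 time points, no missing values."""
    values = np.array(
        [
            [0.1, 0.9, 0.2, 0.8, 0.15, 0.85],
            [-0.5, 0.5, -0.4, 0.6, -0.45, 0.55],
            [1.0, 1.1, 1.2, 0.0, 0.1, 0.2],
        ]
    )
    return ExpressionDataset(
        name="tiny",
        genes=["A", "B", "C"],
        timepoints=[f"T{i}" for i in range(1, 7)],
        values=values,
    )


@pytest.fixture
def default_params():
    return InferenceParams(accuracy=0.75, scp=0.95, max_delay=3)


@pytest.fixture(scope="session")
def noiseless_truth():
    """Study conditions for recovery checks: 12 genes, 20 time points, K=3,
    five two-sided rules planted at delays 0-3, zero noise."""
    return generate(seed=1)


def write_tsv(path, genes, timepoints, rows):
    """Write a minimal expression TSV; rows are per-gene cell-token lists."""
    lines = ["gene\t" + "\t".join(timepoints)]
    for g, row in zip(genes, rows):
        lines.append(g + "\t" + "\t".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path
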