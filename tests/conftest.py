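import numpy as np
import pandas as pd
import pytest

from stresstox.lfq_stats import IntensityMatrix


@pytest.fixture
def toy_matrix_4v4():
    """20-protein, 4-vs-4 log2 matrix with no missing values."""
    rng = np.random.default_rng(42)
    samples = [f"c{i}" for i in range(4)] + [f"t{i}" for i in range(4)]
    vals = rng.normal(25.0, 2.0, (20, 8))
    vals[:5, 4:] += 5.0  # a handful of real shifts
    df = pd.DataFrame(vals, index=[f"P{i:03d}" for i in range(20)], columns=samples)
    group_of = {s: ("ctrl" if s.startswith("c") else "trt") for s in samples}
    return IntensityMatrix(values=df, group_of=group_of, log2_applied=True)


@pytest.fixture
def protein_groups_tsv(tmp_path):
    """Minimal 3-protein MaxQuant-dialect table with one zero cell."""
    path = tmp_path / "proteinGroups.tsv"
    path.write_text(
        "Protein IDs\tLFQ intensity s1\tLFQ intensity s2\n"
        "A\t100\t200\n"
        "B\t0\t300\n"
        "C\t150\t250\n"
    )
    return path
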