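import numpy as np
import pandas as pd
import pytest

from tfdyngrn.datamodel import ExpressionMatrix, Regulon, SampleDesign


@pytest.fixture
def tiny_design() -> SampleDesign:
    """One patient, both conditions, 2 replicates at days 1 and 4."""
    rows = []
    for cond, tag in (("autologous", "auto"), ("monoculture", "mono")):
        for day in (1, 4):
            for rep in (1, 2):
                rows.append((f"p1_{tag}_d{day}_r{rep}", "p1", cond, day, rep))
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "patient", "condition", "day", "replicate"])
    )


@pytest.fixture
def tiny_counts(tiny_design) -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(12)]
    data = pd.DataFrame(
        rng.integers(1, 50, size=(12, 8)), index=genes, columns=tiny_design.sample_ids
    )
    return ExpressionMatrix(data, layer="counts")


@pytest.fixture
def tiny_regulon() -> Regulon:
    rows = [
        ("TF1", "g0", 1, 1.0), ("TF1", "g1", 1, 1.0), ("TF1", "g2", -1, 1.0),
        ("TF1", "g3", 1, 1.0), ("TF1", "g4", 1, 0.5),
        ("TF2", "g5", -1, 1.0), ("TF2", "g6", 1, 1.0), ("TF2", "g7", 1, 1.0),
        ("TF2", "g8", -1, 1.0), ("TF2", "g9", 1, 1.0),
    ]
    return Regulon(pd.DataFrame(rows, columns=["tf", "target", "mode", "weight"]))
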