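import numpy as np
import pandas as pd
import pytest

from tnlineage.count_io import CountTable, GeneAnnotation


def make_table(counts: dict, days=None, hosts=None, kinds=None, conditions=None,
               positions=None) -> CountTable:
    """Assemble a small CountTable from a {sample_id: [counts...]} dict."""
    count_df = pd.DataFrame(counts)
    n = len(count_df)
    positions = positions if positions is not None else [100 * (i + 1) for i in range(n)]
    ids = [f"chr1:{p}:+" for p in positions]
    count_df.index = pd.Index(ids, name="lineage_id")
    lineages = pd.DataFrame({"contig": "chr1", "position": positions, "strand": "+"},
                            index=count_df.index)
    sample_ids = list(counts)
    samples = pd.DataFrame({
        "host_id": hosts or {s: f"m{i}" for i, s in enumerate(sample_ids)},
        "day": days or {s: 4.0 for s in sample_ids},
        "condition": conditions or {s: "HF/HS" for s in sample_ids},
        "kind": kinds or {s: "fecal" for s in sample_ids},
        "species_library": "synthetic",
    })
    samples.index.name = "sample_id"
    return CountTable(count_df.astype(np.int64), lineages, samples).validate()


@pytest.fixture
def toy_table():
    """3 lineages x 2 fecal samples with known depths (40, 400)."""
    return make_table({"s1": [10, 30, 0], "s2": [10, 90, 300]})


@pytest.fixture
def genes():
    return [
        GeneAnnotation("geneA", "chr1", 100, 150, "+", fitness_determinant=True),
        GeneAnnotation("geneB", "chr1", 250, 400, "+", fitness_determinant=False),
    ]
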