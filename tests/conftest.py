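import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from euseq.containers import CountMatrix


def make_count_matrix(counts: dict, classes: dict | None = None,
                      lengths: dict | None = None,
                      conditions: dict | None = None) -> CountMatrix:
    """Small literal CountMatrix; one ERCC row is appended when absent so the
    spike-in invariant holds."""
    df = pd.DataFrame(counts).T
    df.index.name = "gene_id"
    if not any(g.startswith("ERCC-") for g in df.index) and not (
        classes and "spikein" in classes.values()
    ):
        df.loc["ERCC-00002"] = 1000
    meta = pd.DataFrame(index=df.index)
    meta["class"] = pd.Series(classes or {}, dtype=object).reindex(df.index)
    meta.loc[meta["class"].isna() & df.index.str.startswith("ERCC-"), "class"] = "spikein"
    meta["class"] = meta["class"].fillna("protein_coding")
    meta["length_bp"] = pd.Series(lengths or {}).reindex(df.index)
    if conditions is None:
        cols = list(df.columns)
        conditions = {c: ("pre_IR" if i < len(cols) / 2 else "post_IR") for i, c in enumerate(cols)}
    design = pd.DataFrame(
        {"condition": pd.Series(conditions), "replicate": 1}
    )
    design.index.name = "sample_id"
    return CountMatrix(counts=df.astype(np.int64), gene_meta=meta, design=design)


@pytest.fixture
def two_sample_matrix():
    return make_count_matrix(
        {"g1": {"s1": 100, "s2": 150}, "g2": {"s1": 10, "s2": 10}, "g3": {"s1": 0, "s2": 5}},
        conditions={"s1": "pre_IR", "s2": "post_IR"},
    )
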