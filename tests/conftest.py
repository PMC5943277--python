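import numpy as np
import pandas as pd
import pytest

from amfniche import classify, readproc
from amfniche.synth import (SynthConfig, make_design, make_reads,
                            make_reference)


@pytest.fixture(scope="session")
def small_cfg():
    """A compact study: 13 AM OTUs, 300 read pairs per sample."""
    return SynthConfig(n_indigenous_otus=10, n_inoculum_otus=3, n_outgroup=3,
                       reads_per_sample=300, read_error_rate=0.01, seed=11)


@pytest.fixture(scope="session")
def reference(small_cfg):
    return make_reference(small_cfg)


@pytest.fixture(scope="session")
def design(small_cfg):
    return make_design(small_cfg)


@pytest.fixture(scope="session")
def reads_truth(small_cfg, reference, design):
    return make_reads(small_cfg, reference, design)


@pytest.fixture(scope="session")
def merged_sample(reads_truth, design):
    """Merged reads of one field sample plus the source of each read."""
    reads, _ = reads_truth
    sid = design["sample_id"].iloc[0]
    merged = []
    for r in reads[sid]:
        m = readproc.merge_pair(readproc.RawReadPair(
            r.read_id, r.seq1, r.qual1, r.seq2, r.qual2))
        if m is not None:
            merged.append(m)
    sources = {r.read_id: r.source for r in reads[sid]}
    return merged, sources


@pytest.fixture(scope="session")
def assigned_sample(merged_sample, reference):
    merged, sources = merged_sample
    return classify.assign_sample(merged, reference), sources


@pytest.fixture()
def toy_metadata():
    """Hand-built two-trial design with yields, for the index functions."""
    rows = []
    for trial, ctrl_yields, inoc_yields in [
            ("T1", (100.0, 110.0), (120.0, 130.0)),
            ("T2", (200.0, 200.0), (180.0, 220.0))]:
        for i, y in enumerate(ctrl_yields):
            rows.append({"sample_id": f"{trial}_C{i}", "trial": trial,
                         "block": f"{trial}_B{i}", "p_level": 0,
                         "inoculated": False, "yield_kg_ha": y})
        for i, y in enumerate(inoc_yields):
            rows.append({"sample_id": f"{trial}_I{i}", "trial": trial,
                         "block": f"{trial}_B{i}", "p_level": 0,
                         "inoculated": True, "yield_kg_ha": y})
    return pd.DataFrame(rows)


def make_table(counts: dict, rarefied=True):
    """OTUTable from {sample: {otu: count}}."""
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    depth = int(df.sum(axis=1).iloc[0]) if rarefied else None
    return classify.OTUTable(df, rarefied=rarefied, depth=depth)
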