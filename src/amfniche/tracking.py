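"""Inoculum tracking: define the inoculum OTU set and sum its reads.

A pure-culture sequencing run of the inoculum defines a set of marker OTUs
(the inoculum "type" OTUs); their summed read abundance in each field
sample tracks the introduced fungus.  Reads of these OTUs cannot be told
apart from indigenous reads of the same OTUs, so the tracked signal is the
combined one — the set is therefore also excluded from indigenous-community
indices downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = ["InoculumOTUSet", "define_inoculum_set", "track"]


@dataclass
class InoculumOTUSet:
    otu_ids: frozenset
    source_sample: str
    min_share: float = 0.0

    def __iter__(self):
        return iter(sorted(self.otu_ids))

    def __len__(self):
        return len(self.otu_ids)


def define_inoculum_set(table, inoculum_sample: str,
                        min_share: float = 0.0) -> InoculumOTUSet:
    """OTUs whose share of the inoculum sample's reads exceeds ``min_share``.

    With the default ``min_share=0`` every OTU detected in the inoculum
    sequencing defines membership.
    """
    counts = table.counts
    if inoculum_sample not in counts.index:
        raise KeyError(f"inoculum sample {inoculum_sample!r} not in table")
    row = counts.loc[inoculum_sample]
    total = row.sum()
    if total == 0:
        raise ValueError(f"inoculum sample {inoculum_sample!r} has no reads")
    ids = frozenset(row.index[row / total > min_share])
    if not ids:
        raise ValueError("no OTU exceeds min_share in the inoculum sample")
    return InoculumOTUSet(ids, inoculum_sample, min_share)


def track(table, otu_set: InoculumOTUSet,
          exclude_samples=()) -> pd.DataFrame:
    """Per-sample tracked reads and share of the inoculum-type OTU set.

    Returns a DataFrame indexed by sample with columns ``tracked_reads``,
    ``total_reads`` and ``share`` (tracked / total).  Expects a rarefied
    table so shares are comparable across samples.
    """
    if not table.rarefied:
        warnings.warn("tracking on a non-rarefied table; shares are not "
                      "depth-normalized")
    counts = table.counts.drop(index=[s for s in exclude_samples
                                      if s in table.counts.index])
    missing = sorted(set(otu_set.otu_ids) - set(counts.columns))
    if missing:
        raise KeyError(f"inoculum OTUs absent from table: {missing}")
    tracked = counts[sorted(otu_set.otu_ids)].sum(axis=1)
    total = counts.sum(axis=1)
    return pd.DataFrame({
        "tracked_reads": tracked.astype(int),
        "total_reads": total.astype(int),
        "share": tracked / total,
    })
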