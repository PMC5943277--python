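"""Quality trimming, length filtering and overlap merging of paired reads.

Implements the pre-processing criteria natively so behaviour is fully
specified here rather than by external tool versions: 3' bases are trimmed
until the terminal base reaches the quality threshold (default QV 30), a
known 5' adapter prefix is removed, reads shorter than the length floor
(default 200 nt) are rejected, and surviving mates are merged over their
best ungapped 3' overlap within [10, 300] nt with quality-aware consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

__all__ = ["RawReadPair", "MergedRead", "quality_trim", "merge_pair",
           "process_sample", "parse_fastq"]

_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


@dataclass
class RawReadPair:
    read_id: str
    seq1: str
    qual1: str   # Phred+33
    seq2: str
    qual2: str


@dataclass
class MergedRead:
    read_id: str
    seq: str
    qual: str
    overlap_len: int

    @property
    def length(self) -> int:
        return len(self.seq)


def parse_fastq(path):
    """Yield (id, seq, qual) records; raises on malformed records."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record at {header!r} in {path}")
            if len(seq) != len(qual):
                raise ValueError(
                    f"sequence/quality length mismatch for record {header[1:]!r}")
            yield header[1:].split()[0], seq, qual


def _phred(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int32) - 33


def quality_trim(seq: str, qual: str, qv_threshold: int = 30,
                 adapter: Optional[str] = None, min_length: int = 200):
    """Trim 3' low-quality tail and 5' adapter; reject short reads.

    Bases are removed from the 3' end until the terminal base has
    QV >= ``qv_threshold``.  If ``adapter`` is given and the read starts
    with it, the prefix is removed.  Returns ``(seq, qual)`` or ``None``
    when the trimmed read is shorter than ``min_length``.
    """
    if len(seq) != len(qual):
        raise ValueError("sequence and quality strings differ in length")
    if adapter and seq.startswith(adapter):
        seq, qual = seq[len(adapter):], qual[len(adapter):]
    q = _phred(qual)
    end = len(seq)
    while end > 0 and q[end - 1] < qv_threshold:
        end -= 1
    seq, qual = seq[:end], qual[:end]
    if len(seq) < min_length:
        return None
    return seq, qual


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@njit(cache=True)
def _best_overlap(a, b, lo, hi):
    """Overlap length in [lo, hi] with fewest mismatches; ties -> longest."""
    best_L, best_m = lo, 1 << 30
    for L in range(lo, hi + 1):
        m = 0
        off = len(a) - L
        for j in range(L):
            if a[off + j] != b[j]:
                m += 1
        if m < best_m or (m == best_m and L > best_L):
            best_m, best_L = m, L
    return best_L, best_m


def merge_pair(pair: RawReadPair, min_overlap: int = 10, max_overlap: int = 300,
               max_mismatch_rate: float = 0.1) -> Optional[MergedRead]:
    """Merge two mates over their best ungapped 3' overlap.

    Mate 2 is reverse-complemented, candidate overlaps within
    ``[min_overlap, max_overlap]`` are scored by mismatch count (ties go to
    the longest overlap), consensus at disagreeing positions takes the base
    with the higher quality (mate 1 on equal quality).  Returns ``None``
    when no candidate overlap has a mismatch rate <= ``max_mismatch_rate``.
    """
    s1, q1 = pair.seq1, pair.qual1
    s2 = _revcomp(pair.seq2)
    q2 = pair.qual2[::-1]
    a = np.frombuffer(s1.encode(), dtype=np.uint8)
    b = np.frombuffer(s2.encode(), dtype=np.uint8)
    hi = min(len(a), len(b), max_overlap)
    if hi < min_overlap:
        return None
    L, mism = _best_overlap(a, b, min_overlap, hi)
    if mism / L > max_mismatch_rate:
        return None
    qa = _phred(q1[len(s1) - L:])
    qb = _phred(q2[:L])
    ov_a = a[len(a) - L:]
    ov_b = b[:L]
    take_b = (ov_a != ov_b) & (qb > qa)
    consensus = np.where(take_b, ov_b, ov_a).astype(np.uint8)
    cons_q = np.maximum(qa, qb)
    seq = s1[:len(s1) - L] + consensus.tobytes().decode() + s2[L:]
    qual = (q1[:len(s1) - L]
            + (cons_q + 33).astype(np.uint8).tobytes().decode()
            + q2[L:])
    return MergedRead(pair.read_id, seq, qual, L)


def process_sample(r1_path, r2_path, qv_threshold: int = 30,
                   adapter: Optional[str] = None, min_length: int = 200,
                   min_overlap: int = 10, max_overlap: int = 300,
                   max_mismatch_rate: float = 0.1):
    """Trim and merge one sample's FASTQ pair.

    Returns ``(merged_reads, counts)`` with counts for input pairs, pairs
    rejected at trimming, pairs rejected at merging, and merged reads;
    ``input == merged + trim_rejected + merge_rejected`` always holds.
    """
    counts = {"input": 0, "trim_rejected": 0, "merge_rejected": 0, "merged": 0}
    merged = []
    it2 = parse_fastq(r2_path)
    for rid1, seq1, qual1 in parse_fastq(r1_path):
        try:
            rid2, seq2, qual2 = next(it2)
        except StopIteration:
            raise ValueError("mate files have unequal record counts") from None
        counts["input"] += 1
        t1 = quality_trim(seq1, qual1, qv_threshold, adapter, min_length)
        t2 = quality_trim(seq2, qual2, qv_threshold, adapter, min_length)
        if t1 is None or t2 is None:
            counts["trim_rejected"] += 1
            continue
        rid = rid1[:-2] if rid1.endswith(("/1", "/2")) else rid1
        pair = RawReadPair(rid, t1[0], t1[1], t2[0], t2[1])
        m = merge_pair(pair, min_overlap, max_overlap, max_mismatch_rate)
        if m is None:
            counts["merge_rejected"] += 1
        else:
            merged.append(m)
            counts["merged"] += 1
    if next(it2, None) is not None:
        raise ValueError("mate files have unequal record counts")
    return merged, counts


def write_fasta(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.seq}\n")
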