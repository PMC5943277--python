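"""Read-to-OTU assignment with dual acceptance criteria, and OTU tables.

Merged amplicon reads are aligned to a two-tier reference set (AM-fungal
OTUs plus a non-glomeromycotinan outgroup) by local affine-gap alignment on
both strands.  A read's best hit is accepted only if it passes all three
criteria — expectation value E <= 1e-100, nucleotide identity >= 95%, and
alignment length >= 330 bp for AM references (>= 220 bp for outgroup
references).  Accepted outgroup reads are recorded but excluded from the AM
community table, which can then be rarefied to a common depth.

The candidate search uses a fast edit-distance prefilter (edlib) to select
which references are scored by the exact Smith-Waterman routine; pass
``exhaustive=True`` to score every reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import edlib
from numba import njit

__all__ = ["AlignmentParams", "HitRecord", "Assignment", "OTUTable",
           "align_read", "assign_read", "assign_sample", "build_otu_table",
           "rarefy"]

_ENC = bytes.maketrans(b"ACGTN", b"\x00\x01\x02\x03\x04")
_NEG = -(10 ** 9)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme and Karlin-Altschul statistics (BLASTN-like defaults)."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5       # penalty for opening a gap (positive)
    gap_extend: int = 2     # penalty per gap column (positive)
    ka_k: float = 0.41
    ka_lambda: float = 0.625

    def __post_init__(self):
        if self.ka_k <= 0 or self.ka_lambda <= 0:
            raise ValueError("Karlin-Altschul K and lambda must be > 0")


@dataclass
class HitRecord:
    read_id: str
    otu_id: str
    group: str            # "AM" or "OUT"
    score: int
    identity: float       # matches / alignment columns (incl. gaps)
    aln_length: int       # alignment columns including gaps
    evalue: float
    strand: str           # "+" or "-"


@dataclass
class Assignment:
    read_id: str
    status: str           # otu id's status: assigned|unassigned_AM_fail|outgroup|no_hit
    otu_id: Optional[str] = None
    hit: Optional[HitRecord] = None


from functools import lru_cache


def encode(seq: str) -> np.ndarray:
    s = seq.upper().encode()
    bad = set(s) - set(b"ACGTN")
    if bad:
        raise ValueError(
            "non-ACGTN characters in sequence: "
            + ", ".join(chr(c) for c in sorted(bad)))
    return np.frombuffer(s.translate(_ENC), dtype=np.int8)


_encode_cached = lru_cache(maxsize=8192)(lambda s: encode(s))

_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp_str(seq: str) -> str:
    return seq.upper().translate(_RC)[::-1]


@njit(cache=True)
def _sw_score(a, b, match, mismatch, gap_open, gap_extend):
    """Best local alignment score, linear memory (no traceback)."""
    m, n = len(a), len(b)
    H = np.zeros(n + 1, np.int64)
    E = np.full(n + 1, _NEG, np.int64)
    best = 0
    for i in range(1, m + 1):
        diag = 0
        F = _NEG
        left = 0
        for j in range(1, n + 1):
            e = E[j] - gap_extend
            eo = H[j] - gap_open - gap_extend
            E[j] = e if e > eo else eo
            f = F - gap_extend
            fo = left - gap_open - gap_extend
            F = f if f > fo else fo
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != 4) else mismatch
            h = diag + s
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            left = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def _sw_traceback(a, b, match, mismatch, gap_open, gap_extend):
    """Full DP with traceback.

    Returns (score, matches, aln_columns) of the best local alignment;
    among equal-scoring cells the first in row-major order is taken.
    """
    m, n = len(a), len(b)
    H = np.zeros((m + 1, n + 1), np.int64)
    E = np.full((m + 1, n + 1), _NEG, np.int64)
    F = np.full((m + 1, n + 1), _NEG, np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = E[i][j - 1] - gap_extend
            eo = H[i][j - 1] - gap_open - gap_extend
            E[i][j] = e if e > eo else eo
            f = F[i - 1][j] - gap_extend
            fo = H[i - 1][j] - gap_open - gap_extend
            F[i][j] = f if f > fo else fo
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != 4) else mismatch
            h = H[i - 1][j - 1] + s
            if E[i][j] > h:
                h = E[i][j]
            if F[i][j] > h:
                h = F[i][j]
            if h < 0:
                h = 0
            H[i][j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback from (bi, bj) until a zero cell
    i, j = bi, bj
    matches = 0
    cols = 0
    state = 0  # 0 = in H, 1 = in E (gap in a), 2 = in F (gap in b)
    while (i > 0 or j > 0):
        if state == 0:
            if H[i][j] == 0:
                break
            s = match if (i > 0 and j > 0 and a[i - 1] == b[j - 1]
                          and a[i - 1] != 4) else mismatch
            if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + s:
                cols += 1
                if a[i - 1] == b[j - 1] and a[i - 1] != 4:
                    matches += 1
                i -= 1
                j -= 1
            elif H[i][j] == E[i][j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            if E[i][j] == H[i][j - 1] - gap_open - gap_extend:
                state = 0
            j -= 1
        else:
            cols += 1
            if F[i][j] == H[i - 1][j] - gap_open - gap_extend:
                state = 0
            i -= 1
    return best, matches, cols


def _evalue(score: int, query_len: int, search_len: int,
            params: AlignmentParams) -> float:
    """E = K * m * n * exp(-lambda * S), computed in log space."""
    log_e = (math.log(params.ka_k * query_len * max(search_len, 1))
             - params.ka_lambda * score)
    if log_e < -700:
        return 0.0
    return math.exp(log_e)


def align_read(read_seq: str, ref_seq: str,
               params: AlignmentParams = AlignmentParams(),
               search_len: Optional[int] = None,
               read_id: str = "", otu_id: str = "",
               group: str = "AM") -> HitRecord:
    """Local alignment of one read against one reference, both strands.

    ``search_len`` is the total reference length of the searched group (the
    n of the E-value search space); defaults to ``len(ref_seq)``.
    """
    if not read_seq or not ref_seq:
        raise ValueError("empty sequence")
    ref = encode(ref_seq)
    best = None
    for strand, rseq in (("+", read_seq), ("-", _revcomp_str(read_seq))):
        a = encode(rseq)
        score, matches, cols = _sw_traceback(
            a, ref, params.match, params.mismatch,
            params.gap_open, params.gap_extend)
        if best is None or score > best[0]:
            best = (score, matches, cols, strand)
    score, matches, cols, strand = best
    n = search_len if search_len is not None else len(ref_seq)
    return HitRecord(
        read_id=read_id, otu_id=otu_id, group=group, score=int(score),
        identity=(matches / cols) if cols else 0.0, aln_length=int(cols),
        evalue=_evalue(int(score), len(read_seq), n, params), strand=strand)


@dataclass(frozen=True)
class AssignmentCriteria:
    """Dual acceptance criteria for best hits."""

    max_evalue: float = 1e-100
    min_identity: float = 0.95
    min_len_am: int = 330
    min_len_out: int = 220

    def __post_init__(self):
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0, 1]")


def _prefilter_candidates(read_seq: str, reference, k_frac: float = 0.35):
    """Edit-distance screen: (record, strand, distance) candidates.

    Keeps every reference whose best-strand infix edit distance is within a
    small margin of the minimum, so the exact scorer still sees ties.
    """
    rc = _revcomp_str(read_seq)
    k = max(8, int(k_frac * len(read_seq)))
    found = []
    for rec in reference.records:
        best_d, best_strand = None, "+"
        for strand, q in (("+", read_seq), ("-", rc)):
            d = edlib.align(q, rec.seq, mode="HW", task="distance", k=k)["editDistance"]
            if d >= 0 and (best_d is None or d < best_d):
                best_d, best_strand = d, strand
        if best_d is not None:
            found.append((rec, best_strand, best_d))
    if not found:
        return []
    dmin = min(d for _, _, d in found)
    return [(rec, s, d) for rec, s, d in found if d <= dmin + 8]


def assign_read(read_seq: str, reference,
                params: AlignmentParams = AlignmentParams(),
                criteria: AssignmentCriteria = AssignmentCriteria(),
                read_id: str = "", exhaustive: bool = False,
                _search_lens=None) -> Assignment:
    """Assign one merged read per the dual-criteria best-hit rule.

    The best hit is the highest-scoring reference (ties broken by lower
    E-value, then lexicographic id).  AM best hits must satisfy all of
    E <= max_evalue, identity >= min_identity and alignment length
    >= min_len_am to be assigned; outgroup best hits use min_len_out.
    A best hit failing its criteria yields ``unassigned_AM_fail`` (AM) or
    ``no_hit`` (outgroup); so does a read with no alignment at all.
    """
    if not reference.records:
        raise ValueError("empty reference set")
    if not any(r.group == "AM" for r in reference.records):
        raise ValueError("reference set has no AM records")
    if _search_lens is None:
        _search_lens = _group_search_lens(reference)
    if exhaustive:
        cands = [(rec, None, 0) for rec in reference.records]
    else:
        cands = _prefilter_candidates(read_seq, reference)
    if not cands:
        return Assignment(read_id, "no_hit")
    if all(strand is not None for _, strand, _ in cands):
        # fast path: score each candidate on its prefilter strand with the
        # linear-memory kernel, then run the traceback only on the winner
        rc = _revcomp_str(read_seq)
        enc = {"+": encode(read_seq), "-": encode(rc)}
        scored = []
        for rec, strand, _d in cands:
            s = _sw_score(enc[strand], _encode_cached(rec.seq), params.match,
                          params.mismatch, params.gap_open, params.gap_extend)
            scored.append((-s, rec.otu_id, rec, strand))
        scored.sort(key=lambda t: t[:2])
        _, _, rec, strand = scored[0]
        score, matches, cols = _sw_traceback(
            enc[strand], _encode_cached(rec.seq), params.match,
            params.mismatch, params.gap_open, params.gap_extend)
        best = HitRecord(
            read_id=read_id, otu_id=rec.otu_id, group=rec.group,
            score=int(score), identity=(matches / cols) if cols else 0.0,
            aln_length=int(cols),
            evalue=_evalue(int(score), len(read_seq),
                           _search_lens[rec.group], params),
            strand=strand)
    else:
        hits = []
        for rec, _strand, _d in cands:
            hits.append(align_read(read_seq, rec.seq, params,
                                   search_len=_search_lens[rec.group],
                                   read_id=read_id, otu_id=rec.otu_id,
                                   group=rec.group))
        hits.sort(key=lambda h: (-h.score, h.evalue, h.otu_id))
        best = hits[0]
    if best.score <= 0:
        return Assignment(read_id, "no_hit")
    ok_e = best.evalue <= criteria.max_evalue
    ok_id = best.identity >= criteria.min_identity
    if best.group == "AM":
        if ok_e and ok_id and best.aln_length >= criteria.min_len_am:
            return Assignment(read_id, "assigned", best.otu_id, best)
        return Assignment(read_id, "unassigned_AM_fail", None, best)
    if ok_e and ok_id and best.aln_length >= criteria.min_len_out:
        return Assignment(read_id, "outgroup", best.otu_id, best)
    return Assignment(read_id, "no_hit", None, best)


def _group_search_lens(reference):
    lens = {"AM": 0, "OUT": 0}
    for r in reference.records:
        lens[r.group] += len(r.seq)
    if lens["OUT"] == 0:
        lens["OUT"] = 1
    return lens


def assign_sample(merged_reads, reference,
                  params: AlignmentParams = AlignmentParams(),
                  criteria: AssignmentCriteria = AssignmentCriteria(),
                  exhaustive: bool = False):
    """Assign a sample's merged reads; returns a list of Assignments."""
    lens = _group_search_lens(reference)
    out = []
    for r in merged_reads:
        seq = r.seq if hasattr(r, "seq") else r
        rid = r.read_id if hasattr(r, "read_id") else ""
        out.append(assign_read(seq, reference, params, criteria,
                               read_id=rid, exhaustive=exhaustive,
                               _search_lens=lens))
    return out


@dataclass
class OTUTable:
    """Samples x OTUs integer read counts, optionally rarefied."""

    counts: pd.DataFrame        # index = samples, columns = OTU ids
    rarefied: bool = False
    depth: Optional[int] = None
    qc: Optional[pd.DataFrame] = None

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def to_tsv(self, path) -> None:
        # rows = OTUs, columns = samples
        self.counts.T.to_csv(path, sep="\t", index_label="otu_id")

    @classmethod
    def from_tsv(cls, path, rarefied: bool = False) -> "OTUTable":
        df = pd.read_csv(path, sep="\t", index_col=0).T
        df.columns.name = None
        df.index.name = None
        depth = int(df.sum(axis=1).iloc[0]) if rarefied and len(df) else None
        return cls(df.astype(int), rarefied=rarefied, depth=depth)


def build_otu_table(assignments_by_sample: dict, otu_ids=None) -> OTUTable:
    """Tabulate AM-assigned reads per (sample, OTU) plus a QC report.

    ``assignments_by_sample`` maps sample id to that sample's list of
    :class:`Assignment`.  Duplicate read ids within a sample raise.
    """
    qc_rows = {}
    counts = {}
    all_otus = set(otu_ids) if otu_ids is not None else set()
    for sample, assignments in assignments_by_sample.items():
        ids = [a.read_id for a in assignments if a.read_id]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate read ids in sample {sample!r}")
        tally = {}
        qc = {"assigned": 0, "unassigned_AM_fail": 0, "outgroup": 0, "no_hit": 0}
        for a in assignments:
            qc[a.status] += 1
            if a.status == "assigned":
                tally[a.otu_id] = tally.get(a.otu_id, 0) + 1
                all_otus.add(a.otu_id)
        counts[sample] = tally
        qc_rows[sample] = qc
    cols = sorted(all_otus)
    df = pd.DataFrame(
        [[counts[s].get(o, 0) for o in cols] for s in counts],
        index=list(counts), columns=cols, dtype=int)
    qc = pd.DataFrame(qc_rows).T
    return OTUTable(df, rarefied=False, qc=qc)


def rarefy(table: OTUTable, depth: int = 10000,
           seed: Optional[int] = None) -> OTUTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    Deterministic under ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    rows = {}
    for sample, row in table.counts.iterrows():
        total = int(row.sum())
        if total < depth:
            warnings.warn(
                f"sample {sample!r} has {total} < {depth} reads; dropped")
            continue
        if total == depth:
            rows[sample] = row.to_numpy()
        else:
            rows[sample] = rng.multivariate_hypergeometric(
                row.to_numpy().astype(np.int64), depth)
    df = pd.DataFrame(rows, index=table.counts.columns).T.astype(int)
    return OTUTable(df, rarefied=True, depth=depth, qc=table.qc)
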