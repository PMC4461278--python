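"""Read-to-panel alignment with affine gap penalties.

Each filtered insert read is aligned end-to-end against every amplicon
reference in both orientations ("glocal" dynamic programming: the read is
global, the reference ends are free) and the highest-scoring (reference,
strand) pair wins. End-to-end read alignment is chosen deliberately: a fully
local alignment soft-clips any negative-scoring terminal segment and thereby
silently censors sequencing errors at read ends, biasing downstream error
rates low; with a short, trusted amplicon panel and reads already trimmed to
the insert, forcing the read through the DP counts every error exactly once.

Gap convention: a length-k gap costs ``gap_open + (k-1)*gap_extend``.
N in the read matches nothing (scores as mismatch) but is emitted as an ``M``
column so that masked bases are never counted as observed substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .io import AmpliconReference, QualityRead, reverse_complement

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i

_OPS_BYTES = b"MXID"


def encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 2
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("penalties must be negative")
        if self.gap_open > self.gap_extend:
            raise ValueError("gap_open must be <= gap_extend")


@dataclass
class AlignmentResult:
    """Assignment of a read to a reference with a per-column operation string.

    ``ops`` is over {M,X,I,D}: M = match column (including read-N columns),
    X = substitution, I = insertion in the read (read bases), D = deletion
    from the reference (reference bases). Coordinates are 0-based half-open
    on the reference. For strand '-', ``ops`` and coordinates describe the
    reverse-complemented read against the forward reference.
    """

    read_id: str
    ref_name: str
    strand: str
    ref_start: int
    ref_end: int
    ops: str
    score: int
    aligned: bool


NEG = -(1 << 28)


@njit(cache=True)
def _glocal_score(q, r, ma, mi, go, ge):  # pragma: no cover - exercised via align_read
    m = q.shape[0]
    n = r.shape[0]
    hm0 = np.zeros(n + 1, np.int32)
    hx0 = np.full(n + 1, NEG, np.int32)
    hy0 = np.full(n + 1, NEG, np.int32)
    hm1 = np.empty(n + 1, np.int32)
    hx1 = np.empty(n + 1, np.int32)
    hy1 = np.empty(n + 1, np.int32)
    for i in range(1, m + 1):
        qi = q[i - 1]
        hm1[0] = NEG
        a = hm0[0] + go
        b = hx0[0] + ge
        c = hy0[0] + go
        hx1[0] = max(a, max(b, c))
        hy1[0] = NEG
        for j in range(1, n + 1):
            s = ma if (qi == r[j - 1] and qi < 4) else mi
            p = hm0[j - 1]
            if hx0[j - 1] > p:
                p = hx0[j - 1]
            if hy0[j - 1] > p:
                p = hy0[j - 1]
            hm1[j] = p + s
            a = hm0[j] + go
            b = hx0[j] + ge
            c = hy0[j] + go
            hx1[j] = max(a, max(b, c))
            a = hm1[j - 1] + go
            b = hy1[j - 1] + ge
            c = hx1[j - 1] + go
            hy1[j] = max(a, max(b, c))
        hm0, hm1 = hm1, hm0
        hx0, hx1 = hx1, hx0
        hy0, hy1 = hy1, hy0
    best = NEG
    for j in range(n + 1):
        v = hm0[j]
        if hx0[j] > v:
            v = hx0[j]
        if v > best:
            best = v
    return best


@njit(cache=True)
def _glocal_traceback(q, r, ma, mi, go, ge):  # pragma: no cover
    m = q.shape[0]
    n = r.shape[0]
    HM = np.full((m + 1, n + 1), NEG, np.int32)
    HX = np.full((m + 1, n + 1), NEG, np.int32)
    HY = np.full((m + 1, n + 1), NEG, np.int32)
    for j in range(n + 1):
        HM[0, j] = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        HX[i, 0] = max(HM[i - 1, 0] + go, max(HX[i - 1, 0] + ge, HY[i - 1, 0] + go))
        for j in range(1, n + 1):
            s = ma if (qi == r[j - 1] and qi < 4) else mi
            p = HM[i - 1, j - 1]
            if HX[i - 1, j - 1] > p:
                p = HX[i - 1, j - 1]
            if HY[i - 1, j - 1] > p:
                p = HY[i - 1, j - 1]
            HM[i, j] = p + s
            HX[i, j] = max(HM[i - 1, j] + go, max(HX[i - 1, j] + ge, HY[i - 1, j] + go))
            HY[i, j] = max(HM[i, j - 1] + go, max(HY[i, j - 1] + ge, HX[i, j - 1] + go))
    best = NEG
    bj = 0
    bstate = 0
    for j in range(n + 1):
        if HM[m, j] > best:
            best = HM[m, j]
            bj = j
            bstate = 0
        if HX[m, j] > best:
            best = HX[m, j]
            bj = j
            bstate = 1
    ops = np.empty(m + n, np.uint8)
    k = 0
    i = m
    j = bj
    state = bstate
    while i > 0:
        if state == 0:
            qi = q[i - 1]
            match = qi == r[j - 1] and qi < 4
            s = ma if match else mi
            if match or qi == 4:
                ops[k] = 0  # M (read N stays M)
            else:
                ops[k] = 1  # X
            k += 1
            prev = HM[i, j] - s
            if HM[i - 1, j - 1] == prev:
                state = 0
            elif HX[i - 1, j - 1] == prev:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 2  # I
            k += 1
            cur = HX[i, j]
            if HM[i - 1, j] + go == cur:
                state = 0
            elif HX[i - 1, j] + ge == cur:
                state = 1
            else:
                state = 2
            i -= 1
        else:
            ops[k] = 3  # D
            k += 1
            cur = HY[i, j]
            if HM[i, j - 1] + go == cur:
                state = 0
            elif HY[i, j - 1] + ge == cur:
                state = 2
            else:
                state = 1
            j -= 1
    return best, ops[:k][::-1].copy(), j, bj


def align_read(
    read: QualityRead,
    refs: list[AmpliconReference],
    scheme: ScoringScheme | None = None,
    min_score_fraction: float = 0.30,
) -> AlignmentResult:
    """Best glocal alignment of ``read`` over all references and both strands.

    Ties break by highest score, then panel order, then '+' strand; the
    result is ``aligned=False`` when the best score falls below
    ``min_score_fraction * match * len(read)``.
    """
    scheme = scheme or ScoringScheme()
    if len(read) == 0 or not refs:
        return AlignmentResult(read.read_id, "", "+", 0, 0, "", 0, False)
    ma, mi, go, ge = scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    queries = {"+": encode(read.bases), "-": encode(reverse_complement(read.bases))}
    best_score = None
    best_key = None
    for idx, ref in enumerate(refs):
        rcodes = encode(ref.seq)
        for strand in ("+", "-"):
            score = int(_glocal_score(queries[strand], rcodes, ma, mi, go, ge))
            if best_score is None or score > best_score:
                best_score = score
                best_key = (idx, strand, rcodes)
    idx, strand, rcodes = best_key
    if best_score < min_score_fraction * scheme.match * len(read):
        return AlignmentResult(read.read_id, refs[idx].name, strand, 0, 0, "",
                               best_score, False)
    score, opcodes, ref_start, ref_end = _glocal_traceback(
        queries[strand], rcodes, ma, mi, go, ge)
    ops = bytes(_OPS_BYTES[c] for c in opcodes).decode("ascii")
    return AlignmentResult(read.read_id, refs[idx].name, strand, int(ref_start),
                           int(ref_end), ops, int(score), True)


def score_from_ops(aln: AlignmentResult, query: str, ref: str,
                   scheme: ScoringScheme | None = None) -> int:
    """Recompute the alignment score from the ops string and the sequences.

    ``query`` is the read in alignment orientation (reverse-complemented for
    strand '-'). M columns holding a read N score as mismatches, matching the
    DP; gap runs cost open + (len-1)*extend, with an I run followed by a D
    run (or vice versa) re-opening.
    """
    scheme = scheme or ScoringScheme()
    score = 0
    i = 0
    j = aln.ref_start
    prev = ""
    for op in aln.ops:
        if op == "M" or op == "X":
            score += scheme.match if (query[i] == ref[j] and query[i] != "N") else scheme.mismatch
            i += 1
            j += 1
        elif op == "I":
            score += scheme.gap_extend if prev == "I" else scheme.gap_open
            i += 1
        elif op == "D":
            score += scheme.gap_extend if prev == "D" else scheme.gap_open
            j += 1
        else:
            raise ValueError(f"invalid op {op!r}")
        prev = op
    return score


def batch_align(
    reads: list[QualityRead],
    refs: list[AmpliconReference],
    scheme: ScoringScheme | None = None,
    min_score_fraction: float = 0.30,
) -> tuple[list[AlignmentResult], dict]:
    """Align a batch and report the alignment rate plus per-(amplicon, strand)
    read counts (the read-distribution summary)."""
    results = [align_read(r, refs, scheme, min_score_fraction) for r in reads]
    n_in = len(results)
    n_aligned = sum(1 for a in results if a.aligned)
    by_amp: dict[str, int] = {}
    for a in results:
        if a.aligned:
            key = f"{a.ref_name}:{a.strand}"
            by_amp[key] = by_amp.get(key, 0) + 1
    stats = {
        "n_input": n_in,
        "n_aligned": n_aligned,
        "alignment_rate_pct": (100.0 * n_aligned / n_in) if n_in else 0.0,
        "by_amplicon_strand": by_amp,
    }
    return results, stats
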