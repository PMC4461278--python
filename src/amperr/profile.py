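"""Error-rate accounting: per-run and per-amplicon substitution/indel rates
and the base-specific substitution matrix.

Rates follow the platform-comparison conventions:

* subst %   = 100 * substituted aligned bases / aligned bases
* indel %   = 100 * (inserted + deleted bases) / aligned bases
* subs/read and indels/read divide by aligned reads

Indels are counted in bases, not events (a 3-base insertion contributes 3),
with event counts kept as a secondary tally. The substitution matrix counts
only reference positions outside homopolymer runs and GC-rich windows, so a
handful of error-prone contexts cannot dominate the base-specific picture;
matrix entry (ref -> read) is 100 * count / non-excluded aligned columns of
that reference base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AlignmentResult
from .io import AmpliconReference, QualityRead, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: transition pairs (purine<->purine, pyrimidine<->pyrimidine), (ref, read)
TRANSITIONS = ((0, 2), (2, 0), (1, 3), (3, 1))


@dataclass(frozen=True)
class ExclusionPolicy:
    """What counts as a homopolymer run or a GC-rich window.

    A 4-base run already measurably perturbs flow-based base calling, hence
    the default ``homopolymer_min_run=4``; GC-rich means any 10-base window
    at >= 80% G+C.
    """

    homopolymer_min_run: int = 4
    gc_window: int = 10
    gc_min_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.homopolymer_min_run < 2:
            raise ValueError("homopolymer_min_run must be >= 2")
        if not (0.0 < self.gc_min_fraction <= 1.0):
            raise ValueError("gc_min_fraction must be in (0, 1]")
        if self.gc_window < 1:
            raise ValueError("gc_window must be positive")


def run_lengths(seq: str) -> np.ndarray:
    """Length of the homopolymer run containing each position."""
    n = len(seq)
    out = np.empty(n, dtype=np.int64)
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        out[i:j] = j - i
        i = j
    return out


def build_exclusion_mask(ref_seq: str, policy: ExclusionPolicy = ExclusionPolicy()) -> np.ndarray:
    """Boolean mask, True where a position is inside a homopolymer run of
    length >= ``homopolymer_min_run`` or inside any ``gc_window``-base window
    with G+C fraction >= ``gc_min_fraction``."""
    n = len(ref_seq)
    mask = run_lengths(ref_seq) >= policy.homopolymer_min_run if n else np.zeros(0, bool)
    w = policy.gc_window
    if n >= w:
        gc = np.frombuffer(ref_seq.encode("ascii"), dtype=np.uint8)
        gc = (gc == ord("G")) | (gc == ord("C"))
        csum = np.concatenate([[0], np.cumsum(gc)])
        need = policy.gc_min_fraction * w
        for start in range(n - w + 1):
            if csum[start + w] - csum[start] >= need - 1e-12:
                mask[start : start + w] = True
    return mask


@dataclass
class ErrorProfile:
    """Count tables for one run, pooled and per amplicon."""

    aligned_bases: int = 0
    aligned_reads: int = 0
    subst_bases: int = 0
    ins_bases: int = 0
    del_bases: int = 0
    ins_events: int = 0
    del_events: int = 0
    masked_cols: int = 0
    subst_matrix_counts: np.ndarray = field(default_factory=lambda: np.zeros((4, 4), np.int64))
    per_base_totals: np.ndarray = field(default_factory=lambda: np.zeros(4, np.int64))
    per_amplicon: dict[str, "ErrorProfile"] = field(default_factory=dict)

    @property
    def indel_bases(self) -> int:
        return self.ins_bases + self.del_bases


def accumulate(profile: ErrorProfile, aln: AlignmentResult, ref: AmpliconReference,
               read: QualityRead) -> ErrorProfile:
    """Tally one aligned read into the profile (pooled and per-amplicon).

    Reverse-strand alignments are tallied in reference coordinates with the
    read bases complemented. Read-N columns count as aligned bases but never
    as substitutions, and are excluded from the matrix denominators.
    """
    if not aln.aligned:
        raise ValueError(f"read {aln.read_id!r}: cannot accumulate an unaligned result")
    ref_span = aln.ops.count("M") + aln.ops.count("X") + aln.ops.count("D")
    if ref_span != aln.ref_end - aln.ref_start:
        raise ValueError(
            f"read {aln.read_id!r}: ops cover {ref_span} reference bases but "
            f"coordinates span {aln.ref_end - aln.ref_start}")
    if aln.ref_end > len(ref.seq):
        raise ValueError(f"read {aln.read_id!r}: alignment exceeds reference {ref.name!r}")

    sub = profile.per_amplicon.setdefault(ref.name, ErrorProfile())
    query = read.bases if aln.strand == "+" else reverse_complement(read.bases)

    targets = (profile, sub)
    for t in targets:
        t.aligned_reads += 1
    i = 0
    j = aln.ref_start
    prev = ""
    for op in aln.ops:
        if op == "M" or op == "X":
            qb = query[i]
            rb = ref.seq[j]
            for t in targets:
                t.aligned_bases += 1
            if qb == "N":
                for t in targets:
                    t.masked_cols += 1
            else:
                if op == "X":
                    for t in targets:
                        t.subst_bases += 1
                if not ref.excluded_mask[j]:
                    ri = _BASE_INDEX[rb]
                    for t in targets:
                        t.per_base_totals[ri] += 1
                        if op == "X":
                            t.subst_matrix_counts[ri, _BASE_INDEX[qb]] += 1
            i += 1
            j += 1
        elif op == "I":
            for t in targets:
                t.ins_bases += 1
                if prev != "I":
                    t.ins_events += 1
            i += 1
        elif op == "D":
            for t in targets:
                t.del_bases += 1
                if prev != "D":
                    t.del_events += 1
            j += 1
        else:
            raise ValueError(f"invalid op {op!r}")
        prev = op
    return profile


def _rate_block(p: ErrorProfile) -> dict:
    defined = p.aligned_reads > 0 and p.aligned_bases > 0
    return {
        "aligned_bases": p.aligned_bases,
        "aligned_reads": p.aligned_reads,
        "subst_bases": p.subst_bases,
        "indel_bases": p.indel_bases,
        "ins_events": p.ins_events,
        "del_events": p.del_events,
        "subst_pct": 100.0 * p.subst_bases / p.aligned_bases if defined else 0.0,
        "indel_pct": 100.0 * p.indel_bases / p.aligned_bases if defined else 0.0,
        "subs_per_read": p.subst_bases / p.aligned_reads if defined else 0.0,
        "indels_per_read": p.indel_bases / p.aligned_reads if defined else 0.0,
        "defined": defined,
    }


def rates(profile: ErrorProfile) -> dict:
    """Derived rate table, pooled and per amplicon. With zero aligned reads
    the rates are reported as 0 with ``defined=False``."""
    out = _rate_block(profile)
    out["per_amplicon"] = {name: _rate_block(p) for name, p in profile.per_amplicon.items()}
    return out


def substitution_matrix(profile: ErrorProfile) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """4x4 percentage matrix, row totals, and per-base column totals.

    ``matrix[i, j]`` = 100 * count(ref base i read as j) / non-excluded
    aligned columns with ref base i; the diagonal is NaN, as are rows whose
    denominator is zero. Row totals are the sum of the off-diagonal entries.
    """
    counts = profile.subst_matrix_counts.astype(float)
    totals = profile.per_base_totals.astype(float)
    matrix = np.full((4, 4), np.nan)
    row_totals = np.full(4, np.nan)
    for i in range(4):
        if totals[i] <= 0:
            continue
        row_totals[i] = 0.0
        for j in range(4):
            if i == j:
                continue
            matrix[i, j] = 100.0 * counts[i, j] / totals[i]
            row_totals[i] += matrix[i, j]
    return matrix, row_totals, profile.per_base_totals.copy()


def classify_transitions(matrix: np.ndarray) -> dict:
    """Mean transition vs transversion rate over the matrix entries.

    Transition rate is the mean of {A->G, G->A, C->T, T->C}; transversion
    rate the mean of the remaining 8 off-diagonal entries. Undefined entries
    count as zero.
    """
    m = np.nan_to_num(np.asarray(matrix, dtype=float), nan=0.0)
    ts = [m[i, j] for i, j in TRANSITIONS]
    tv = [m[i, j] for i in range(4) for j in range(4)
          if i != j and (i, j) not in TRANSITIONS]
    return {
        "transition_rate": float(np.mean(ts)),
        "transversion_rate": float(np.mean(tv)),
    }
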