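"""Quality masking and read filtering, with per-position quality summaries.

The rules are the published amplicon-QC recipe: every base below Phred 20 is
replaced by N (its quality score is kept), then reads with mean Phred < 25 or
more than 6 N bases are removed. The mean is the arithmetic mean of Phred
scores over all positions, masked ones included, matching the
``min_qual_mean`` semantics of the standard read-filtering tools. Boundary
semantics are strict: Q20 stays unmasked, mean exactly 25 is kept, exactly
6 Ns is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import QualityRead


@dataclass(frozen=True)
class FilterPolicy:
    mask_below: int = 20
    min_mean_q: float = 25.0
    max_n: int = 6

    def __post_init__(self) -> None:
        if self.mask_below < 0 or self.min_mean_q < 0 or self.max_n < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class QcSummary:
    """Per-position quality statistics and the read-length histogram."""

    per_position_quality: pd.DataFrame
    read_length_histogram: dict[int, int]
    reads_in: int
    reads_kept: int


def mask_low_quality(read: QualityRead, policy: FilterPolicy = FilterPolicy()) -> QualityRead:
    """Replace every base with quality < ``mask_below`` by N.

    Qualities and length are unchanged; idempotent by construction.
    """
    low = read.quals < policy.mask_below
    if not low.any():
        return read
    buf = bytearray(read.bases, "ascii")
    for i in np.flatnonzero(low):
        buf[i] = 78  # ord('N')
    return QualityRead(
        read.read_id, buf.decode("ascii"), read.quals,
        sample_id=read.sample_id, orientation=read.orientation,
        untrimmed=read.untrimmed,
    )


def filter_read(read: QualityRead, policy: FilterPolicy = FilterPolicy()) -> tuple[bool, str | None]:
    """Keep/drop decision for a masked read: ``(True, None)`` or
    ``(False, reason)`` with reason in {empty, low_mean_q, too_many_n}."""
    if len(read) == 0:
        return False, "empty"
    if float(read.quals.mean()) < policy.min_mean_q:
        return False, "low_mean_q"
    if read.bases.count("N") > policy.max_n:
        return False, "too_many_n"
    return True, None


def summarize_quality(reads: list[QualityRead], policy: FilterPolicy | None = None) -> QcSummary:
    """Per-position mean/quartiles over reads covering each position, plus
    the read-length histogram.

    If ``policy`` is given, ``reads_kept`` counts reads passing
    :func:`filter_read`; otherwise it equals ``reads_in``.
    """
    reads = list(reads)
    n = len(reads)
    hist: dict[int, int] = {}
    for r in reads:
        hist[len(r)] = hist.get(len(r), 0) + 1
    if n == 0:
        per_pos = pd.DataFrame(
            columns=["position", "count", "mean", "q25", "median", "q75"])
        return QcSummary(per_pos, hist, 0, 0)

    maxlen = max(len(r) for r in reads)
    mat = np.full((n, maxlen), np.nan)
    for i, r in enumerate(reads):
        mat[i, : len(r)] = r.quals
    count = np.sum(~np.isnan(mat), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0)
        q25, med, q75 = np.nanpercentile(mat, [25, 50, 75], axis=0)
    per_pos = pd.DataFrame({
        "position": np.arange(1, maxlen + 1),
        "count": count.astype(int),
        "mean": mean,
        "q25": q25,
        "median": med,
        "q75": q75,
    })
    kept = n
    if policy is not None:
        kept = sum(1 for r in reads if filter_read(r, policy)[0])
    return QcSummary(per_pos, hist, n, kept)
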