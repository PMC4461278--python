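"""Two-step PCR library model: construct layout, barcodes, demultiplex, trim.

The modelled construct is

    adapter5 + barcode + linker_fwd + insert + rc(linker_rev) + rc(adapter3)

i.e. first-round gene-specific primers carry universal linker tails and the
second-round primers fuse platform adapters and a sample barcode onto those
tails. Reverse-orientation molecules are represented by reverse-complementing
the insert inside the same layout, so demultiplexing and trimming are
orientation-blind and the aligner decides strand.

The packaged presets use placeholder adapter/linker sequences with the
documented structure and lengths (10 bp MIDs for 454 and IonTorrent, a
concatenated 16 bp dual index for Illumina); the pipeline is fully
sequence-agnostic given a ConstructSpec. The universal forward linker carries
a 4 bp G homopolymer, mirroring the short G stretch present in the real
two-step design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import ceil
from pathlib import Path

import numpy as np

from .io import QualityRead, REF_ALPHABET, reverse_complement

PLATFORM_TAGS = ("flx454", "pgm", "miseq")

#: placeholder platform sequences (documented structure/lengths, synthetic content)
_PRESET_PARTS = {
    "flx454": dict(
        adapter5="CCTATCCCATGTCAGACGTTCGATA",
        adapter3="GATGTACGTCTAAGCACTGACCTGA",
        barcode_len=10,
    ),
    "pgm": dict(
        adapter5="CCATCTCATCGCAGTACGTACGCTA",
        adapter3="CCACTACGCCTCAGATGTTCAGTCA",
        barcode_len=10,
    ),
    "miseq": dict(
        adapter5="AATGATACGGCTACCACGTCAGATC",
        adapter3="CAAGCAGAAGTCGCATACGAGTACT",
        barcode_len=16,
    ),
}
_UNIV_LINKER = "TACGGGGTCATCAGTCGACT"  # univ-linker, contains the 4 bp G stretch
_T7_LINKER = "GATCCTAGTTGACACTGTCA"  # T7-linker


@dataclass(frozen=True)
class ConstructSpec:
    """Layout of the two-step construct for one platform."""

    platform_tag: str
    adapter5: str
    adapter3: str
    linker_fwd: str
    linker_rev: str
    barcode_len: int

    def __post_init__(self) -> None:
        if self.platform_tag not in PLATFORM_TAGS:
            raise ValueError(f"unknown platform tag {self.platform_tag!r}")
        for name in ("adapter5", "adapter3", "linker_fwd", "linker_rev"):
            seq = getattr(self, name)
            if not seq or not REF_ALPHABET.issuperset(seq):
                raise ValueError(f"{name} must be a non-empty ACGT sequence")
        if self.barcode_len < 4:
            raise ValueError("barcode_len must be >= 4")

    @property
    def barcode_offset(self) -> int:
        return len(self.adapter5)

    @property
    def insert_offset(self) -> int:
        return len(self.adapter5) + self.barcode_len + len(self.linker_fwd)

    @property
    def flank3_len(self) -> int:
        return len(self.linker_rev) + len(self.adapter3)


def construct_preset(platform_tag: str) -> ConstructSpec:
    """Packaged construct layout for a platform tag."""
    if platform_tag not in _PRESET_PARTS:
        raise ValueError(f"unknown platform tag {platform_tag!r}")
    parts = _PRESET_PARTS[platform_tag]
    return ConstructSpec(
        platform_tag=platform_tag,
        adapter5=parts["adapter5"],
        adapter3=parts["adapter3"],
        linker_fwd=_UNIV_LINKER,
        linker_rev=_T7_LINKER,
        barcode_len=parts["barcode_len"],
    )


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N never matches."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


@dataclass
class BarcodeSet:
    """sample_id -> barcode map with a guaranteed-unambiguous mismatch radius.

    The constructor enforces pairwise Hamming distance > 2*max_mismatch so
    that a read window is within ``max_mismatch`` of at most one barcode.
    """

    entries: dict[str, str]
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty barcode set")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be non-negative")
        lengths = {len(b) for b in self.entries.values()}
        if len(lengths) != 1:
            raise ValueError("all barcodes must have the same length")
        for bc in self.entries.values():
            if not REF_ALPHABET.issuperset(bc):
                raise ValueError(f"barcode {bc!r} has non-ACGT characters")
        items = list(self.entries.items())
        for i, (si, bi) in enumerate(items):
            for sj, bj in items[i + 1 :]:
                d = hamming(bi, bj)
                if d <= 2 * self.max_mismatch:
                    raise ValueError(
                        f"barcodes {si!r}/{sj!r} at Hamming distance {d} are "
                        f"ambiguous at max_mismatch={self.max_mismatch}"
                    )

    @property
    def barcode_len(self) -> int:
        return len(next(iter(self.entries.values())))


def make_barcode_set(n_samples: int, length: int, max_mismatch: int = 1,
                     seed: int = 7) -> BarcodeSet:
    """Deterministically generate ``n_samples`` barcodes of ``length`` bases
    with pairwise distance > 2*max_mismatch (greedy seeded search)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    chosen: list[str] = []
    attempts = 0
    while len(chosen) < n_samples:
        cand = "".join(rng.choice(bases, size=length))
        if all(hamming(cand, b) > 2 * max_mismatch for b in chosen):
            chosen.append(cand)
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not build a barcode set; relax parameters")
    entries = {f"S{i + 1:02d}": bc for i, bc in enumerate(chosen)}
    return BarcodeSet(entries, max_mismatch=max_mismatch)


def read_barcode_sheet(path: str | Path, max_mismatch: int = 1) -> BarcodeSet:
    """Read a ``sample_id<TAB>barcode`` sheet."""
    entries: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, bc = line.split("\t")[:2]
            if sample in entries:
                raise ValueError(f"duplicate sample {sample!r} in {path}")
            entries[sample] = bc.upper()
    return BarcodeSet(entries, max_mismatch=max_mismatch)


def write_barcode_sheet(barcodes: BarcodeSet, path: str | Path) -> None:
    with open(path, "w") as out:
        for sample, bc in barcodes.entries.items():
            out.write(f"{sample}\t{bc}\n")


def assemble_construct(spec: ConstructSpec, barcode: str, insert: str) -> str:
    """Full construct sequence for one molecule (insert given in the
    orientation it was amplified in)."""
    if len(barcode) != spec.barcode_len:
        raise ValueError(
            f"barcode length {len(barcode)} != spec.barcode_len {spec.barcode_len}")
    if not REF_ALPHABET.issuperset(insert):
        raise ValueError("insert must be over {A,C,G,T}")
    return (spec.adapter5 + barcode + spec.linker_fwd + insert
            + reverse_complement(spec.linker_rev) + reverse_complement(spec.adapter3))


def demultiplex(read: QualityRead, barcodes: BarcodeSet, spec: ConstructSpec) -> str | None:
    """Assign a read to a sample by its barcode window, or None (unassigned).

    The window sits at the fixed offset after adapter5. N bases count as
    mismatches. The BarcodeSet distance invariant guarantees at most one
    barcode within ``max_mismatch``, so assignment is unambiguous.
    """
    start = spec.barcode_offset
    end = start + barcodes.barcode_len
    if len(read.bases) < end:
        return None
    window = read.bases[start:end]
    for sample, bc in barcodes.entries.items():
        if hamming(window, bc) <= barcodes.max_mismatch:
            return sample
    return None


def _allowed_mismatches(length: int, max_mismatch: int) -> int:
    # tolerance of max_mismatch per started 10 bases
    return max_mismatch * ceil(length / 10)


def _locate_pattern(pattern: str, region: str) -> tuple[int, int, int]:
    """Best placement of ``pattern`` inside ``region`` (pattern consumed
    end-to-end, free region ends, affine gaps). Returns (score, start, end)
    in region coordinates."""
    from .align import _glocal_traceback, encode

    score, _, start, end = _glocal_traceback(encode(pattern), encode(region), 2, -4, -6, -1)
    return int(score), int(start), int(end)


def _locate_pattern_last(pattern: str, region: str) -> tuple[int, int, int]:
    """Like :func:`_locate_pattern` but ties prefer the rightmost placement
    (a degenerate insert may itself contain the linker sequence; the flank
    copy is always the last one)."""
    score, rstart, rend = _locate_pattern(pattern[::-1], region[::-1])
    return score, len(region) - rend, len(region) - rstart


def _pattern_threshold(length: int, max_mismatch: int) -> int:
    """Minimum acceptable placement score: the perfect score minus the
    penalty of ``max_mismatch`` mismatch-equivalents per started 10 bases
    (an indel counts roughly like a mismatch), with one unit of slack."""
    allowance = (2 - (-4)) * ceil(length / 10) * max_mismatch + 2
    return 2 * length - allowance


def trim_construct(read: QualityRead, spec: ConstructSpec, max_mismatch: int = 1) -> QualityRead:
    """Strip the 5' adapter+barcode+linker and, when present, the 3'
    linker+adapter; qualities are trimmed in lockstep.

    The 5' adapter must be recognisable within ``max_mismatch``
    mismatch-equivalents per 10 bases (indels count); otherwise the read is
    returned unchanged with ``untrimmed=True`` and alignment decides its
    fate. Both cut points are found by aligning the linker patterns
    (indel-tolerant), so an indel inside the flank does not shift the cut
    and leak flank bases into the insert — which would otherwise masquerade
    as sequencing errors downstream. Truncated reads that never reach the 3'
    linker are 5'-trimmed only.
    """
    la = len(spec.adapter5)
    if len(read.bases) < spec.insert_offset + 1:
        return replace(read, untrimmed=True)
    score, _, _ = _locate_pattern(spec.adapter5, read.bases[: la + 4])
    if score < _pattern_threshold(la, max_mismatch):
        return replace(read, untrimmed=True)

    # 5' cut: locate the forward linker just after the barcode
    lf = spec.linker_fwd
    w5 = la + spec.barcode_len
    region_start = max(la, w5 - 4)
    score, _, end = _locate_pattern(lf, read.bases[region_start : w5 + len(lf) + 8])
    cut5 = region_start + end if score >= _pattern_threshold(len(lf), max_mismatch) \
        else spec.insert_offset

    # 3' cut: locate the reverse-complemented reverse linker near the read end
    pat = reverse_complement(spec.linker_rev)
    cut3 = len(read.bases)
    w3 = max(cut5, len(read.bases) - spec.flank3_len - 30)
    region = read.bases[w3:]
    if len(region) >= len(pat) - 2:
        score, start, _ = _locate_pattern_last(pat, region)
        if score >= _pattern_threshold(len(pat), max_mismatch):
            cut3 = w3 + start
    return QualityRead(
        read.read_id,
        read.bases[cut5:cut3],
        read.quals[cut5:cut3],
        sample_id=read.sample_id,
        orientation=read.orientation,
    )
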