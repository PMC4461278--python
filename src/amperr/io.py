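"""Core read/reference types and the standard formats the pipeline touches.

Reads are plain Phred+33 FASTQ (four-line records); the reference panel is an
uppercase ACGT FASTA. Reports externalise the run summary, per-amplicon rates
and the base-specific substitution matrix as deterministic TSV tables plus a
machine-readable JSON twin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

READ_ALPHABET = frozenset("ACGTN")
REF_ALPHABET = frozenset("ACGT")
ORIENTATIONS = ("forward", "reverse", "unknown")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class QualityRead:
    """A sequence with per-base Phred scores and provenance metadata.

    ``quals`` is a uint8 array of the same length as ``bases`` with values in
    [0, 60] (Sanger/Phred+33 range used by all current platforms).
    """

    read_id: str
    bases: str
    quals: np.ndarray
    sample_id: str | None = None
    orientation: str = "unknown"
    untrimmed: bool = False

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.uint8)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.bases)} != "
                f"quality length {len(self.quals)}"
            )
        if self.quals.size and int(self.quals.max()) > 60:
            raise ValueError(
                f"read {self.read_id!r}: Phred score {int(self.quals.max())} > 60; "
                "input must be Phred+33 (Sanger) encoded — Phred+64 is not supported"
            )
        if not READ_ALPHABET.issuperset(self.bases):
            bad = sorted(set(self.bases) - READ_ALPHABET)
            raise ValueError(f"read {self.read_id!r}: invalid base(s) {bad}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"invalid orientation {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AmpliconReference:
    """A named amplicon target with its substitution-matrix exclusion mask.

    ``excluded_mask[i]`` is True where position ``i`` lies in a homopolymer
    run or a GC-rich window and must not enter the substitution-matrix
    tallies (it still contributes to the overall error rates).
    """

    name: str
    seq: str
    excluded_mask: np.ndarray

    def __post_init__(self) -> None:
        self.excluded_mask = np.asarray(self.excluded_mask, dtype=bool)
        if not REF_ALPHABET.issuperset(self.seq):
            bad = sorted(set(self.seq) - REF_ALPHABET)
            raise ValueError(f"reference {self.name!r}: invalid base(s) {bad}")
        if len(self.excluded_mask) != len(self.seq):
            raise ValueError(f"reference {self.name!r}: mask/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


def read_fastq(path: str | Path) -> Iterator[QualityRead]:
    """Stream Phred+33 FASTQ records in file order.

    A record whose sequence and quality lines disagree in length, or whose
    qualities decode above Phred 60 (a Phred+64 file, typically), is a hard
    error naming the record.
    """
    with open(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                quals = np.array(rec.letter_annotations["phred_quality"], dtype=np.int64)
                if quals.size and quals.max() > 60:
                    raise ValueError(
                        f"record {rec.id!r}: quality above Phred 60 — "
                        "only Phred+33 (Sanger) encoding is accepted"
                    )
                yield QualityRead(rec.id, str(rec.seq).upper(), quals.astype(np.uint8))
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc


def write_fastq(reads: Iterable[QualityRead], path: str | Path) -> None:
    """Write four-line Phred+33 FASTQ, byte-deterministic."""
    with open(path, "w") as out:
        for read in reads:
            qline = "".join(chr(q + 33) for q in read.quals)
            out.write(f"@{read.read_id}\n{read.bases}\n+\n{qline}\n")


def read_reference_panel(path: str | Path, exclusion_policy=None) -> list[AmpliconReference]:
    """Load a FASTA amplicon panel; case is normalised to uppercase.

    Duplicate record names and ambiguity codes other than ACGT are errors.
    Each reference gets an exclusion mask from
    :func:`amperr.profile.build_exclusion_mask` under ``exclusion_policy``
    (defaults to the packaged policy).
    """
    from .profile import ExclusionPolicy, build_exclusion_mask

    policy = exclusion_policy or ExclusionPolicy()
    refs: list[AmpliconReference] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate reference name {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not REF_ALPHABET.issuperset(seq):
            bad = sorted(set(seq) - REF_ALPHABET)
            raise ValueError(f"reference {rec.id!r}: invalid base(s) {bad}")
        refs.append(AmpliconReference(rec.id, seq, build_exclusion_mask(seq, policy)))
    return refs


def write_panel_fasta(refs: Iterable[AmpliconReference], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for ref in refs:
            out.write(f">{ref.name}\n")
            for i in range(0, len(ref.seq), width):
                out.write(ref.seq[i : i + width] + "\n")


def format_pct(x: float) -> str:
    """Round half-up to two decimals, matching the print precision of the
    published platform-comparison tables (e.g. 0.0709 -> '0.07')."""
    return str(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# reports


def write_report(profile, outdir: str | Path, *, qc_summary=None, stage_counts=None,
                 align_stats=None) -> dict:
    """Write the report bundle for a finalised profile.

    Emits ``run_rates.tsv`` (overall rates), ``amplicon_rates.tsv`` (one row
    per amplicon), ``subst_matrix.tsv`` (correct base x read-as percentages)
    and ``report.json``. Identical profiles produce byte-identical files.
    Returns the JSON document as a dict.
    """
    from .profile import rates, substitution_matrix, classify_transitions, BASES

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rate = rates(profile)
    header = ("aligned_bases\taligned_reads\tsubst\tsubst_read\tsubst_pct\t"
              "indels\tindels_read\tindels_pct\n")

    def _row(r) -> str:
        return "\t".join([
            str(r["aligned_bases"]), str(r["aligned_reads"]), str(r["subst_bases"]),
            format_pct(r["subs_per_read"]), format_pct(r["subst_pct"]),
            str(r["indel_bases"]), format_pct(r["indels_per_read"]),
            format_pct(r["indel_pct"]),
        ])

    with open(outdir / "run_rates.tsv", "w") as out:
        out.write("run\t" + header)
        out.write("pooled\t" + _row(rate) + "\n")

    with open(outdir / "amplicon_rates.tsv", "w") as out:
        out.write("amplicon\t" + header)
        for name in sorted(rate["per_amplicon"]):
            out.write(f"{name}\t" + _row(rate["per_amplicon"][name]) + "\n")

    matrix, totals, base_totals = substitution_matrix(profile)
    with open(outdir / "subst_matrix.tsv", "w") as out:
        out.write("correct_base\t" + "\t".join(BASES) + "\tTotal\n")
        for i, b in enumerate(BASES):
            cells = []
            for j in range(4):
                if i == j:
                    cells.append("")
                elif np.isnan(matrix[i, j]):
                    cells.append("NA")
                else:
                    cells.append(format_pct(matrix[i, j]) + "%")
            tot = "NA" if np.isnan(totals[i]) else format_pct(totals[i]) + "%"
            out.write(f"{b}\t" + "\t".join(cells) + f"\t{tot}\n")

    doc: dict = {
        "rates": _jsonable(rate),
        "substitution_matrix": {
            "percent": [[None if np.isnan(v) else v for v in row] for row in matrix],
            "row_totals": [None if np.isnan(v) else v for v in totals],
            "per_base_totals": [int(v) for v in base_totals],
            "bases": list(BASES),
        },
        "transition_transversion": _jsonable(classify_transitions(matrix)),
    }
    if stage_counts is not None:
        doc["stage_counts"] = _jsonable(stage_counts)
    if align_stats is not None:
        doc["alignment"] = _jsonable(align_stats)
    if qc_summary is not None:
        doc["qc"] = {
            "reads_in": qc_summary.reads_in,
            "reads_kept": qc_summary.reads_kept,
            "read_length_histogram": {str(k): int(v) for k, v in
                                      sorted(qc_summary.read_length_histogram.items())},
        }
        qc_summary.per_position_quality.to_csv(
            outdir / "qc_per_position.tsv", sep="\t", index=False, float_format="%.4f")

    with open(outdir / "report.json", "w") as out:
        json.dump(doc, out, indent=1, sort_keys=True)
        out.write("\n")
    return doc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
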