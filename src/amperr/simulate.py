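"""Synthetic sequencing-run generator with full ground truth.

Each simulated read is a two-step PCR construct (adapter + barcode + linker +
insert + linker + adapter) carrying a platform-style error profile:

* substitutions as independent Bernoulli draws per template base, with an
  optional 4x4 conditional bias matrix (e.g. transition-heavy for
  pyrosequencing, transversion-heavy for dye-terminator chemistry);
* single-base indels as independent Bernoulli draws per template base, with
  the per-base probability scaled by ``homopolymer_indel_factor**(run-1)``
  inside homopolymer runs — the dominant error mode of flow-based platforms;
* platform-like read-length models (fixed, or full-length with a truncated
  geometric short-read tail) and quality-score models (flat, declining,
  noisy).

Every injected event is logged with template and reference coordinates, so
pipeline estimates can be checked against ground truth by exact recounting.
Replaying the log against the templates reproduces each emitted read
byte-for-byte. Quality scores are cosmetic by default (all >= 30, so the
quality filter keeps everything) unless a degraded quality model is chosen
deliberately to exercise the filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import AmpliconReference, QualityRead, reverse_complement
from .library import BarcodeSet, ConstructSpec, assemble_construct
from .profile import run_lengths

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# --- length models ---------------------------------------------------------


@dataclass(frozen=True)
class FixedLength:
    """Emit the first ``n`` template bases (or the whole construct if shorter)."""

    n: int


@dataclass(frozen=True)
class TruncatedLength:
    """Full nominal length with probability ``keep_full``, otherwise a
    geometric short-read tail of mean ``tail_mean`` truncated bases."""

    n: int
    keep_full: float = 0.55
    tail_mean: float = 170.0
    min_len: int = 30


# --- quality models --------------------------------------------------------


@dataclass(frozen=True)
class FlatQuality:
    q: int = 38


@dataclass(frozen=True)
class DecliningQuality:
    q_start: int = 38
    slope: float = 0.015  # Phred units lost per base


@dataclass(frozen=True)
class NoisyQuality:
    mean: float = 32.0
    sd: float = 2.5


def uniform_bias() -> np.ndarray:
    """Unbiased substitution target matrix: each wrong base at 1/3."""
    m = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(m, 0.0)
    return m


@dataclass
class PlatformErrorModel:
    """Per-base error behaviour of one platform run."""

    subst_rate: float
    indel_rate: float
    subst_bias: np.ndarray = field(default_factory=uniform_bias)
    homopolymer_indel_factor: float = 1.0
    indel_extend_p: float = 0.0  # geometric continuation; 0 -> single-base indels
    length_model: FixedLength | TruncatedLength = field(default_factory=lambda: FixedLength(400))
    quality_model: FlatQuality | DecliningQuality | NoisyQuality = field(default_factory=FlatQuality)

    def __post_init__(self) -> None:
        self.subst_bias = np.asarray(self.subst_bias, dtype=float)
        if not (0.0 <= self.subst_rate <= 1.0 and 0.0 <= self.indel_rate <= 1.0):
            raise ValueError("error rates must be probabilities")
        if self.subst_bias.shape != (4, 4):
            raise ValueError("subst_bias must be 4x4")
        if np.any(np.abs(np.diag(self.subst_bias)) > 1e-12):
            raise ValueError("subst_bias diagonal must be zero")
        if not np.allclose(self.subst_bias.sum(axis=1), 1.0):
            raise ValueError("subst_bias rows must sum to 1")
        if self.homopolymer_indel_factor <= 0:
            raise ValueError("homopolymer_indel_factor must be positive")
        if min(self.indel_rate, 0.5) / 2.0 >= 0.99:
            raise ValueError("indel rate would shrink reads below one base")


#: Table-like substitution-bias presets. The miseq rows follow the observed
#: transversion-heavy pattern (A->C, T->G dominant); the flow-based platforms
#: are transition-dominant.
_TRANSITION_BIAS = np.array([
    # to:  A     C     G     T
    [0.00, 0.05, 0.90, 0.05],  # A
    [0.05, 0.00, 0.05, 0.90],  # C
    [0.90, 0.05, 0.00, 0.05],  # G
    [0.05, 0.90, 0.05, 0.00],  # T
])
_PGM_BIAS = np.array([
    [0.00, 0.15, 0.70, 0.15],
    [0.15, 0.00, 0.15, 0.70],
    [0.70, 0.15, 0.00, 0.15],
    [0.15, 0.70, 0.15, 0.00],
])
_MISEQ_BIAS = np.array([
    [0.0000, 0.5625, 0.3125, 0.1250],
    [0.6667, 0.0000, 0.1111, 0.2222],
    [0.3000, 0.2000, 0.0000, 0.5000],
    [0.1765, 0.2353, 0.5882, 0.0000],
])


def preset(platform_tag: str) -> PlatformErrorModel:
    """Packaged per-platform error model at the published run-level rates:
    454 GS FLX subst 0.07% / indel 0.18%, IonTorrent PGM subst 0.13% /
    indel 0.60%, Illumina MiSeq subst 1.53% / indel 0.04%."""
    if platform_tag == "flx454":
        return PlatformErrorModel(
            subst_rate=0.0007, indel_rate=0.0018,
            subst_bias=_TRANSITION_BIAS, homopolymer_indel_factor=1.8,
            length_model=FixedLength(500),
            quality_model=DecliningQuality(38, 0.015),
        )
    if platform_tag == "pgm":
        return PlatformErrorModel(
            subst_rate=0.0013, indel_rate=0.0060,
            subst_bias=_PGM_BIAS, homopolymer_indel_factor=1.6,
            length_model=TruncatedLength(380, keep_full=0.55, tail_mean=170.0),
            quality_model=NoisyQuality(32.0, 2.5),
        )
    if platform_tag == "miseq":
        return PlatformErrorModel(
            subst_rate=0.0153, indel_rate=0.0004,
            subst_bias=_MISEQ_BIAS, homopolymer_indel_factor=1.0,
            length_model=FixedLength(250),
            quality_model=FlatQuality(38),
        )
    raise ValueError(f"unknown platform tag {platform_tag!r}")


@dataclass
class GroundTruthLog:
    """Per-read and per-event record of everything the simulator injected."""

    seed: int
    run_threshold: int
    reads: list[dict] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    totals: dict = field(default_factory=dict)

    def reads_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.reads)

    def events_frame(self) -> pd.DataFrame:
        cols = ["read_id", "kind", "template_pos", "ref_pos", "ref_base",
                "obs_ref", "emitted"]
        return pd.DataFrame(self.events, columns=cols)


def simulate_run(
    refs: list[AmpliconReference],
    spec: ConstructSpec,
    barcodes: BarcodeSet,
    model: PlatformErrorModel,
    n_reads: int,
    seed: int,
    ref_weights: np.ndarray | None = None,
    sample_weights: np.ndarray | None = None,
    run_threshold: int = 4,
) -> tuple[list[QualityRead], GroundTruthLog]:
    """Generate ``n_reads`` construct reads with injected errors.

    Fully reproducible given ``seed``: one pseudo-random stream drives every
    choice in a fixed order. Amplicon, sample and strand are drawn uniformly
    unless weights are given. Returns the reads and the ground-truth log;
    ``run_threshold`` sets which homopolymer run length counts as "inside a
    run" for the log's indel-exposure tallies.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if barcodes.barcode_len != spec.barcode_len:
        raise ValueError("barcode length does not match the construct spec")
    rng = np.random.default_rng(seed)
    samples = list(barcodes.entries)
    off5 = spec.insert_offset

    # template cache: (ref_idx, strand, sample) -> construct data
    cache: dict[tuple, tuple] = {}

    def _template(ref_i: int, strand: str, sample: str):
        key = (ref_i, strand, sample)
        if key not in cache:
            ref = refs[ref_i]
            insert = ref.seq if strand == "+" else reverse_complement(ref.seq)
            construct = assemble_construct(spec, barcodes.entries[sample], insert)
            runs = run_lengths(construct)
            cache[key] = (construct, runs, len(ref.seq))
        return cache[key]

    reads: list[QualityRead] = []
    log = GroundTruthLog(seed=seed, run_threshold=run_threshold)
    tot = dict(template_bases=0, insert_bases=0,
               sub_total=0, ins_total=0, del_total=0,
               sub_insert=0, ins_insert=0, del_insert=0,
               bases_in_runs=0, bases_out_runs=0,
               indels_in_runs=0, indels_out_runs=0)

    lm = model.length_model
    qm = model.quality_model
    factor = model.homopolymer_indel_factor

    for i in range(n_reads):
        ref_i = int(rng.choice(len(refs), p=ref_weights))
        sample = samples[int(rng.choice(len(samples), p=sample_weights))]
        strand = "+" if rng.random() < 0.5 else "-"
        construct, runs_full, insert_len = _template(ref_i, strand, sample)

        if isinstance(lm, FixedLength):
            L = min(lm.n, len(construct))
        else:
            L = min(lm.n, len(construct))
            if rng.random() >= lm.keep_full:
                L = max(lm.min_len, L - int(rng.geometric(1.0 / lm.tail_mean)))
        template = construct[:L]
        runs_t = runs_full[:L]

        def _ref_coord(k: int) -> tuple[int, str]:
            """Map template position to (ref_pos, ref_base) in reference
            orientation; (-1, '') for flank positions."""
            if off5 <= k < off5 + insert_len:
                p = k - off5
                if strand == "-":
                    p = insert_len - 1 - p
                return p, refs[ref_i].seq[p]
            return -1, ""

        read_id = f"sim{i:07d}"
        buf = bytearray(template, "ascii")
        n_sub = n_ins = n_del = 0

        # substitutions
        sub_pos = np.flatnonzero(rng.random(L) < model.subst_rate)
        for k in sub_pos:
            k = int(k)
            orig = template[k]
            row = model.subst_bias["ACGT".index(orig)]
            new = str(rng.choice(_BASES, p=row))
            buf[k] = ord(new)
            n_sub += 1
            ref_pos, ref_base = _ref_coord(k)
            obs_ref = (new if strand == "+" else _COMP[new]) if ref_pos >= 0 else ""
            log.events.append(dict(read_id=read_id, kind="sub", template_pos=k,
                                   ref_pos=ref_pos, ref_base=ref_base,
                                   obs_ref=obs_ref, emitted=new))
            tot["sub_total"] += 1
            if ref_pos >= 0:
                tot["sub_insert"] += 1

        # indels (probability scaled inside homopolymer runs)
        if model.indel_rate > 0:
            p_pos = np.minimum(model.indel_rate * factor ** (runs_t - 1), 0.5)
            indel_pos = np.flatnonzero(rng.random(L) < p_pos)
        else:
            indel_pos = np.empty(0, dtype=int)
        indels: list[tuple[int, str, str]] = []  # (pos, kind, ins_bases)
        for k in indel_pos:
            k = int(k)
            is_ins = rng.random() < 0.5
            length = 1
            while model.indel_extend_p > 0 and rng.random() < model.indel_extend_p:
                length += 1
            ref_pos, ref_base = _ref_coord(k)
            in_run = runs_t[k] >= run_threshold
            if is_ins:
                ins = "".join(rng.choice(_BASES, size=length))
                indels.append((k, "ins", ins))
                n_ins += length
                obs_ref = (ins if strand == "+" else reverse_complement(ins)) if ref_pos >= 0 else ""
                log.events.append(dict(read_id=read_id, kind="ins", template_pos=k,
                                       ref_pos=ref_pos, ref_base=ref_base,
                                       obs_ref=obs_ref, emitted=ins))
                tot["ins_total"] += length
                if ref_pos >= 0:
                    tot["ins_insert"] += length
            else:
                indels.append((k, "del", ""))
                n_del += 1
                log.events.append(dict(read_id=read_id, kind="del", template_pos=k,
                                       ref_pos=ref_pos, ref_base=ref_base,
                                       obs_ref="", emitted=""))
                tot["del_total"] += 1
                if ref_pos >= 0:
                    tot["del_insert"] += 1
            if in_run:
                tot["indels_in_runs"] += 1
            else:
                tot["indels_out_runs"] += 1

        if indels:
            parts: list[bytes] = []
            prev = 0
            for k, kind, ins in sorted(indels):
                parts.append(bytes(buf[prev:k]))
                if kind == "ins":
                    parts.append(ins.encode("ascii"))
                    parts.append(bytes(buf[k : k + 1]))
                prev = k + 1
            parts.append(bytes(buf[prev:]))
            emitted = b"".join(parts).decode("ascii")
        else:
            emitted = buf.decode("ascii")

        quals = _draw_quals(qm, len(emitted), rng)
        reads.append(QualityRead(read_id, emitted, quals))

        cov = max(0, min(L, off5 + insert_len) - off5)
        in_runs = int(np.sum(runs_t >= run_threshold))
        tot["template_bases"] += L
        tot["insert_bases"] += cov
        tot["bases_in_runs"] += in_runs
        tot["bases_out_runs"] += L - in_runs
        log.reads.append(dict(
            read_id=read_id, ref_name=refs[ref_i].name, sample_id=sample,
            strand=strand, template_len=L, emitted_len=len(emitted),
            insert_cov=cov, n_sub=n_sub, n_ins=n_ins, n_del=n_del,
        ))

    log.totals = tot
    return reads, log


def _draw_quals(qm, n: int, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=np.uint8)
    if isinstance(qm, FlatQuality):
        q = np.full(n, qm.q, dtype=float)
    elif isinstance(qm, DecliningQuality):
        q = qm.q_start - qm.slope * np.arange(n)
    else:
        q = rng.normal(qm.mean, qm.sd, size=n)
    return np.clip(np.rint(q), 2, 40).astype(np.uint8)


def replay(log: GroundTruthLog, refs: list[AmpliconReference], spec: ConstructSpec,
           barcodes: BarcodeSet) -> list[str]:
    """Rebuild every emitted read sequence from templates plus logged events.

    Byte equality with the simulator's FASTQ output is the log-fidelity
    invariant.
    """
    refs_by_name = {r.name: r for r in refs}
    events_by_read: dict[str, list[dict]] = {}
    for ev in log.events:
        events_by_read.setdefault(ev["read_id"], []).append(ev)
    out = []
    for rec in log.reads:
        ref = refs_by_name[rec["ref_name"]]
        insert = ref.seq if rec["strand"] == "+" else reverse_complement(ref.seq)
        construct = assemble_construct(spec, barcodes.entries[rec["sample_id"]], insert)
        template = construct[: rec["template_len"]]
        buf = bytearray(template, "ascii")
        indels = []
        for ev in events_by_read.get(rec["read_id"], []):
            if ev["kind"] == "sub":
                buf[ev["template_pos"]] = ord(ev["emitted"])
            else:
                indels.append((ev["template_pos"], ev["kind"], ev["emitted"]))
        if indels:
            parts: list[bytes] = []
            prev = 0
            for k, kind, ins in sorted(indels):
                parts.append(bytes(buf[prev:k]))
                if kind == "ins":
                    parts.append(ins.encode("ascii"))
                    parts.append(bytes(buf[k : k + 1]))
                prev = k + 1
            parts.append(bytes(buf[prev:]))
            out.append(b"".join(parts).decode("ascii"))
        else:
            out.append(buf.decode("ascii"))
    return out


def homopolymer_indel_enrichment(log: GroundTruthLog) -> dict:
    """One-sided test that the realized indel rate inside homopolymer runs
    exceeds the rate outside.

    Uses the log's exposure tallies; the p-value is a binomial test of the
    in-run indel count against the out-of-run rate.
    """
    t = log.totals
    rate_out = t["indels_out_runs"] / t["bases_out_runs"] if t["bases_out_runs"] else 0.0
    rate_in = t["indels_in_runs"] / t["bases_in_runs"] if t["bases_in_runs"] else 0.0
    if t["bases_in_runs"] == 0 or rate_out == 0.0:
        pvalue = 1.0 if t["indels_in_runs"] == 0 else 0.0
    else:
        pvalue = stats.binomtest(t["indels_in_runs"], t["bases_in_runs"],
                                 rate_out, alternative="greater").pvalue
    return {"rate_in_runs": rate_in, "rate_out_runs": rate_out,
            "bases_in_runs": t["bases_in_runs"], "pvalue": float(pvalue)}


def write_truth(log: GroundTruthLog, outdir: str | Path) -> None:
    """Write the ground-truth log as TSV (reads + events) with a seed header."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# seed={log.seed} run_threshold={log.run_threshold}\n"
    with open(outdir / "truth_reads.tsv", "w") as out:
        out.write(header)
        log.reads_frame().to_csv(out, sep="\t", index=False)
    with open(outdir / "truth_events.tsv", "w") as out:
        out.write(header)
        log.events_frame().to_csv(out, sep="\t", index=False)
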