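"""Packaged synthetic amplicon reference panel.

Five exon-sized targets (325-370 bp) named after the CREBBP exonic amplicons
they emulate in size and context. The sequences are SYNTHETIC, generated from
a fixed pseudo-random stream — they are stand-ins for the real exon
sequences, not copies of them — but they reproduce the error-relevant
features of the real panel: E16 carries a 7-base A homopolymer and E18_01 a
13-base T homopolymer (the contexts that dominate flow-based indel errors),
and E30_02 carries a GC-rich stretch that exercises the GC-window exclusion.
"""

from __future__ import annotations

import numpy as np

from .io import AmpliconReference
from .profile import ExclusionPolicy, build_exclusion_mask

_PANEL_SEED = 20150625

#: name -> (length, planted motif, planted position)
_LAYOUT = (
    ("E16", 350, "AAAAAAA", 150),
    ("E18_01", 370, "TTTTTTTTTTTTT", 200),
    ("E26", 341, None, 0),
    ("E30_01", 325, None, 0),
    ("E30_02", 360, "GCGGCCGCGGCCG", 120),
)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def synthetic_panel(exclusion_policy: ExclusionPolicy | None = None) -> list[AmpliconReference]:
    """The packaged five-amplicon panel (deterministic)."""
    policy = exclusion_policy or ExclusionPolicy()
    rng = np.random.default_rng(_PANEL_SEED)
    refs = []
    for name, length, motif, pos in _LAYOUT:
        seq = _random_seq(rng, length)
        if motif:
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        refs.append(AmpliconReference(name, seq, build_exclusion_mask(seq, policy)))
    return refs
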