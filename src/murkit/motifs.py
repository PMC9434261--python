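"""Sequence utilities supporting the MurE specificity argument.

MurE ligases that incorporate meso-DAP at stem position 3 carry a C-terminal
motif (canonically DNPR) whose arginine hydrogen-bonds to, and stabilizes,
the D-stereocenter of DAP.  Charge-conserving variants occur (DNPK in many
seed plants, DNPA in Poaceae, DNSR in a few Pinaceae, DDPR in Thermotoga),
so the scanner accepts a named pattern set plus a generalized class
[D][ND][PS][RKA].

Also here: trimming a chloroplast transit peptide at a given 1-based residue
(mature moss MurE starts at Leu63) and a documented Needleman-Wunsch percent
identity.  Printed identity percentages from alignment web services are not
reproduced: this is a self-contained global-alignment identity with stated
parameters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "VALID_RESIDUES",
    "DEFAULT_MOTIFS",
    "GENERALIZED_MOTIF",
    "SequenceRecord",
    "MotifHit",
    "scan_dap_motif",
    "trim_transit_peptide",
    "pairwise_identity",
    "read_fasta",
    "write_fasta",
]

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")

#: Named stem-position-3 specificity motifs.
DEFAULT_MOTIFS: tuple[str, ...] = ("DNPR", "DNPK", "DNPA", "DNSR", "DDPR")

#: Generalized motif class covering the named variants.
GENERALIZED_MOTIF = "[D][ND][PS][RKA]"


@dataclass(frozen=True)
class SequenceRecord:
    """An amino-acid sequence (one-letter, 20 standard residues plus X)."""

    identifier: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        for i, ch in enumerate(self.sequence, start=1):
            if ch not in VALID_RESIDUES:
                raise ValueError(
                    f"invalid residue {ch!r} at position {i} in {self.identifier!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence; ``start`` is 1-based."""

    pattern: str
    start: int
    match: str


def scan_dap_motif(
    seq: SequenceRecord, patterns: "Sequence[str] | None" = None
) -> list[MotifHit]:
    """All non-overlapping motif hits, left to right.

    At each position the named patterns are tried first (reported under their
    own token); any other match of the generalized class is reported under
    the class token.  Overlaps resolve to the leftmost hit.
    """
    named = tuple(patterns) if patterns is not None else DEFAULT_MOTIFS
    width = {len(p) for p in named}
    if len(width) != 1:
        raise ValueError("all motif patterns must share one width")
    w = width.pop()
    general = re.compile(GENERALIZED_MOTIF) if patterns is None else None
    hits: list[MotifHit] = []
    s = seq.sequence
    i = 0
    while i + w <= len(s):
        window = s[i : i + w]
        if window in named:
            hits.append(MotifHit(pattern=window, start=i + 1, match=window))
            i += w
        elif general is not None and general.fullmatch(window):
            hits.append(MotifHit(pattern=GENERALIZED_MOTIF, start=i + 1, match=window))
            i += w
        else:
            i += 1
    return hits


def trim_transit_peptide(seq: SequenceRecord, start: int) -> SequenceRecord:
    """Suffix from 1-based residue ``start`` (inclusive), e.g. Leu63 for PpMurE."""
    if not 1 <= start <= len(seq):
        raise ValueError(f"start {start} out of range 1..{len(seq)}")
    return SequenceRecord(
        identifier=f"{seq.identifier}_L{start}" if start > 1 else seq.identifier,
        sequence=seq.sequence[start - 1 :],
        source=seq.source,
    )


def _aligner() -> PairwiseAligner:
    # global alignment; match +1, mismatch 0, affine gaps open -2 / extend -0.5
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -2.0
    a.extend_gap_score = -0.5
    return a


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Percent identity over all columns of one optimal global alignment."""
    if not len(a) or not len(b):
        raise ValueError("sequences must be non-empty")
    aln = _aligner().align(a.sequence, b.sequence)[0]
    counts = aln.counts()
    columns = aln.length
    return counts.identities / columns * 100.0


def read_fasta(path) -> list[SequenceRecord]:
    return [
        SequenceRecord(
            identifier=rec.id, sequence=str(rec.seq).upper(), source=rec.description
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    SeqIO.write(
        (
            SeqRecord(Seq(r.sequence), id=r.identifier, description=r.source)
            for r in records
        ),
        str(path),
        "fasta",
    )
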