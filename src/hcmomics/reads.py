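"""Aligned-read primitives shared by the allele-classification rules.

A read is stored in its aligned form: a 1-based reference start plus a
CIGAR-style operator list. Only five operators are supported — ``M``
(aligned match/mismatch), ``I`` (insertion to the reference), ``D``
(deletion from the reference), ``N`` (skipped reference, i.e. a spliced-out
intron) and ``S`` (soft clip). Conforming input from an end-to-end aligner
contains no soft clips, but the type tolerates them so that the >90 %
aligned-base gate can reject such reads rather than crash on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: CIGAR operators that consume read (query) bases.
QUERY_OPS = frozenset("MIS")
#: CIGAR operators that consume reference bases.
REF_OPS = frozenset("MDN")

_VALID_OPS = frozenset("MIDNS")


@dataclass(slots=True)
class AlignedRead:
    """A single mapped read.

    Parameters
    ----------
    name : str
        Read name, unique within a batch up to PCR duplicates.
    chrom : str
        Reference sequence name.
    start : int
        1-based leftmost aligned reference position.
    cigar : tuple of (str, int)
        Ordered operator list, e.g. ``(("M", 30), ("N", 300), ("M", 45))``
        for a spliced read.
    bases : str
        Read base sequence (query order).
    mapq : int
        Mapping quality.
    tags : dict
        Optional SAM auxiliary tags (used to carry simulation truth).
    """

    name: str
    chrom: str
    start: int
    cigar: tuple
    bases: str
    mapq: int = 60
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        qlen = 0
        for op, ln in self.cigar:
            if op not in _VALID_OPS:
                raise ValueError(f"unsupported CIGAR operator {op!r} in read {self.name}")
            if ln <= 0:
                raise ValueError(f"non-positive CIGAR length in read {self.name}")
            if op in QUERY_OPS:
                qlen += ln
        if qlen != len(self.bases):
            raise ValueError(
                f"read {self.name}: CIGAR consumes {qlen} query bases but "
                f"sequence has {len(self.bases)}"
            )

    @property
    def end(self) -> int:
        """1-based inclusive rightmost aligned reference position."""
        return self.start + sum(ln for op, ln in self.cigar if op in REF_OPS) - 1

    def cigar_string(self) -> str:
        return "".join(f"{ln}{op}" for op, ln in self.cigar)


def ref_blocks(read: AlignedRead) -> tuple:
    """Reference intervals covered by aligned-match bases, 1-based closed.

    Adjacent ``M`` segments separated only by an insertion coalesce into one
    block; deletions and skips split blocks.
    """
    blocks = []
    ref = read.start
    for op, ln in read.cigar:
        if op == "M":
            if blocks and blocks[-1][1] + 1 == ref:
                blocks[-1] = (blocks[-1][0], ref + ln - 1)
            else:
                blocks.append((ref, ref + ln - 1))
            ref += ln
        elif op in ("D", "N"):
            ref += ln
    return tuple(blocks)


def skip_blocks(read: AlignedRead) -> tuple:
    """Reference intervals removed by ``N`` (splice) operators, 1-based closed."""
    out = []
    ref = read.start
    for op, ln in read.cigar:
        if op == "N":
            out.append((ref, ref + ln - 1))
            ref += ln
        elif op in ("M", "D"):
            ref += ln
    return tuple(out)


def base_at(read: AlignedRead, pos: int) -> Optional[str]:
    """Read base aligned to reference position ``pos`` (1-based).

    Returns ``None`` when ``pos`` falls in a deletion, a skipped intron,
    or outside the read's aligned span.
    """
    ref = read.start
    q = 0
    for op, ln in read.cigar:
        if op == "M":
            if ref <= pos < ref + ln:
                return read.bases[q + pos - ref]
            ref += ln
            q += ln
        elif op in ("I", "S"):
            q += ln
        else:  # D or N
            if ref <= pos < ref + ln:
                return None
            ref += ln
    return None


def aligned_fraction(read: AlignedRead) -> float:
    """Fraction of read bases consumed by aligned-match operators.

    Insertions and soft clips count against the read; skips do not consume
    read bases and are therefore neutral. Total read bases is the
    denominator.
    """
    if not read.bases:
        raise ValueError(f"read {read.name} has zero length")
    matched = sum(ln for op, ln in read.cigar if op == "M")
    return matched / len(read.bases)


def spans_continuously(read: AlignedRead, left: int, right: int) -> bool:
    """True if a single aligned-match block covers both ``left`` and ``right``.

    Used to decide whether a read runs gaplessly across an intron/exon
    boundary (no splice, deletion or clip in between).
    """
    for b_start, b_end in ref_blocks(read):
        if b_start <= left and right <= b_end:
            return True
    return False
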