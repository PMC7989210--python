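"""Variant and locus descriptions for allele-specific read classification.

The three heterozygous truncating *MYBPC3* variant classes handled here are

``snv``
    A single-nucleotide variant with no effect on splicing
    (c.2827C>T / rs387907267 in the study this package models).
``duplication``
    A single-base duplication adjacent to an intron donor site that
    abolishes correct splicing of that intron (c.2373dupG / rs397515963,
    which disrupts splicing of intron 23).
``splice_acceptor_snv``
    An SNV in the acceptor dinucleotide of an intron, causing intron
    retention (c.927-2A>G / rs397516082, which disrupts splicing of
    intron 11 so that mutant transcripts run through the intron 11 /
    exon 12 boundary).

Coordinates are 1-based throughout; intervals are closed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

VAR_CLASSES = ("snv", "duplication", "splice_acceptor_snv")

#: classes whose mutant allele changes the splice pattern of an intron
SPLICE_AFFECTING = ("duplication", "splice_acceptor_snv")


@dataclass(frozen=True)
class VariantSpec:
    """One heterozygous variant and the geometry its assignment rules need.

    ``flank_left``/``flank_right`` (10 bases each) are required for the
    duplication class only: the ChIP rule matches the exact wildtype or
    mutant sequence with 10 surrounding bases. ``intron_start``/``intron_end``
    delimit the affected intron for the splice-affecting classes;
    ``downstream_exon_start`` marks the first base of the exon following the
    broken acceptor (splice_acceptor_snv only).
    """

    id: str
    cdna_name: str
    var_class: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    flank_left: Optional[str] = None
    flank_right: Optional[str] = None
    intron_start: Optional[int] = None
    intron_end: Optional[int] = None
    downstream_exon_start: Optional[int] = None

    def __post_init__(self) -> None:
        if self.var_class not in VAR_CLASSES:
            raise ValueError(f"unknown variant class {self.var_class!r}")
        if self.var_class == "duplication":
            if not (self.flank_left and self.flank_right):
                raise ValueError("duplication variants require 10-base flanks")
            if len(self.flank_left) != 10 or len(self.flank_right) != 10:
                raise ValueError("flanks must be exactly 10 bases")
        elif self.flank_left or self.flank_right:
            raise ValueError("flanks are only meaningful for duplication variants")
        if self.var_class in SPLICE_AFFECTING:
            if self.intron_start is None or self.intron_end is None:
                raise ValueError(f"{self.var_class} requires the affected intron interval")
            if not (self.intron_start - 1 <= self.pos <= self.intron_end + 1):
                raise ValueError("variant position must lie within or adjacent to the affected intron")
        if self.var_class == "splice_acceptor_snv" and self.downstream_exon_start is None:
            raise ValueError("splice_acceptor_snv requires downstream_exon_start")

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def affected_intron(self) -> Optional[Tuple[int, int]]:
        if self.var_class in SPLICE_AFFECTING:
            return (self.intron_start, self.intron_end)
        return None

    def wildtype_window(self) -> str:
        """Exact 21-base wildtype sequence: 10-base flanks around the site."""
        if self.var_class != "duplication":
            raise ValueError("sequence windows are defined for duplication variants only")
        return self.flank_left + self.ref_allele + self.flank_right

    def mutant_window(self) -> str:
        """Exact mutant sequence with 10-base flanks around the duplicated base."""
        if self.var_class != "duplication":
            raise ValueError("sequence windows are defined for duplication variants only")
        return self.flank_left + self.alt_allele + self.flank_right


@dataclass(frozen=True)
class LocusTemplate:
    """A synthetic locus: exon/intron geometry plus the wildtype sequence.

    ``offset`` is the 1-based genomic coordinate of ``wildtype_sequence[0]``;
    exon and intron blocks are 1-based closed intervals in the same space.
    The mutant haplotype is obtained by applying ``variant`` to the wildtype
    sequence.
    """

    reference_name: str
    exon_blocks: tuple
    intron_blocks: tuple
    wildtype_sequence: str
    variant: VariantSpec
    offset: int = 1

    def __post_init__(self) -> None:
        blocks = sorted(self.exon_blocks + self.intron_blocks)
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if s2 <= e1:
                raise ValueError("exon and intron blocks must be disjoint and sorted")
        for s, e in blocks:
            if s > e:
                raise ValueError("malformed block")
        if len(self.wildtype_sequence) != self.span:
            raise ValueError("wildtype_sequence length must equal the locus span")
        if not (self.locus_start <= self.variant.pos <= self.locus_end):
            raise ValueError("variant position falls outside the locus")

    @property
    def locus_start(self) -> int:
        return self.offset

    @property
    def locus_end(self) -> int:
        return self.offset + len(self.wildtype_sequence) - 1

    @property
    def span(self) -> int:
        blocks = self.exon_blocks + self.intron_blocks
        return max(e for _, e in blocks) - min(s for s, _ in blocks) + 1

    def base(self, pos: int) -> str:
        """Wildtype base at 1-based genomic position ``pos``."""
        return self.wildtype_sequence[pos - self.offset]

    def slice(self, start: int, end: int) -> str:
        """Wildtype sequence for the closed interval [start, end]."""
        return self.wildtype_sequence[start - self.offset : end - self.offset + 1]

    def mutant_sequence(self) -> str:
        """The mutant genomic haplotype in wildtype coordinates.

        For SNV classes the variant base is substituted; for the duplication
        class the extra copy of the duplicated base is inserted after
        ``variant.pos`` (so mutant genomic coordinates downstream of the
        site are shifted by +1 relative to the reference).
        """
        v = self.variant
        i = v.pos - self.offset
        wt = self.wildtype_sequence
        # for the duplication class alt carries the extra copy (e.g. G -> GG),
        # so the single replacement below covers both substitution and insertion
        return wt[:i] + v.alt_allele + wt[i + 1 :]
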