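"""Allele-specific read classification at heterozygous *MYBPC3* variants.

The pipeline is: deduplicate aligned reads, assign every retained read to
the wildtype or mutant allele with per-variant, per-assay rules, and tally
the mutant:wildtype ratio.

Deduplication
-------------
Reads that aligned to the same genomic interval *and* carry identical bases
at every non-indel variant position are PCR duplicates and collapse to a
single representative (the highest-mapq copy; ties broken by read name).

ChIP-seq assignment (genomic DNA, no splicing)
----------------------------------------------
* Reads must have more than 90 % of their bases aligned to the genome.
* SNV-like variants: the base aligned to the variant position decides —
  reference base → wildtype, alternate base → mutant; a deleted/skipped
  position or a third allele leaves the read unassigned.
* The single-base duplication: the read must contain, contiguously, the
  exact wildtype (flank + base + flank, 21 bp) or mutant
  (flank + duplicated bases + flank, 22 bp) sequence window.

RNA-seq assignment (spliced reads)
----------------------------------
* ``snv`` (no splice change): same base rule as ChIP.
* ``duplication`` (broken donor-side splicing): a read whose splice gap
  removes exactly the affected intron (correct donor *and* acceptor) is
  wildtype; a read spliced at exactly one of the correct donor/acceptor
  coordinates — but not both — is mutant.
* ``splice_acceptor_snv`` (intron retention): a read splicing out exactly
  the affected intron is wildtype; a read running gaplessly through the
  intron/exon boundary and covering the variant position is classified by
  the base it carries there.

Anything else is unassigned; unassigned reads never enter the ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

from .reads import (
    AlignedRead,
    aligned_fraction,
    base_at,
    ref_blocks,
    skip_blocks,
    spans_continuously,
)
from .variants import VariantSpec

CALLS = ("wildtype", "mutant", "unassigned")

#: rule labels recorded on every call, for audit
REASONS = (
    "snv_base",
    "flank_match",
    "junction_spliced",
    "one_sided_splice",
    "intron_runthrough_base",
    "no_overlap",
    "aligned_fraction_fail",
    "third_allele",
)


@dataclass(frozen=True, slots=True)
class AlleleCall:
    read_name: str
    variant_id: str
    assay: str
    call: str
    reason: str


@dataclass
class AlleleCounts:
    """Per (variant, assay) tallies after deduplication.

    ``ratio_percent`` is 100 * mutant / wildtype, the convention used to
    report allelic imbalance; it is ``None`` when no wildtype reads were
    seen (division undefined), which a control sample without the mutant
    haplotype never triggers.
    """

    variant_id: str
    assay: str
    n_wildtype: int = 0
    n_mutant: int = 0
    n_unassigned: int = 0
    n_duplicates_removed: int = 0

    @property
    def n_evaluated(self) -> int:
        return self.n_wildtype + self.n_mutant + self.n_unassigned

    @property
    def ratio_percent(self) -> Optional[float]:
        if self.n_wildtype == 0:
            return None
        return round(100.0 * self.n_mutant / self.n_wildtype, 1)

    @property
    def mutant_fraction(self) -> Optional[float]:
        """mutant / (mutant + wildtype), the quantity recovered in simulations."""
        assigned = self.n_mutant + self.n_wildtype
        if assigned == 0:
            return None
        return self.n_mutant / assigned


def allelic_ratio(counts: AlleleCounts) -> Optional[float]:
    """Mutant:wildtype ratio as a percentage, one decimal; None if undefined."""
    ratio = counts.ratio_percent
    if ratio is None:
        warnings.warn(
            f"{counts.variant_id}/{counts.assay}: no wildtype reads, "
            "mutant:wildtype ratio undefined",
            stacklevel=2,
        )
    return ratio


# ---------------------------------------------------------------------------
# deduplication


def _dedup_key(read: AlignedRead, anchor_positions: Sequence[int]) -> tuple:
    bases = tuple(base_at(read, p) for p in anchor_positions)
    return (read.chrom, ref_blocks(read), bases)


def deduplicate(
    reads: Sequence[AlignedRead], variants: Sequence[VariantSpec]
) -> Tuple[List[AlignedRead], int]:
    """Collapse PCR duplicates; returns (retained reads, number removed).

    Identity is (aligned reference interval, bases aligned to every
    non-indel variant position — including "no base" when the read does not
    cover a position). The retained representative is the highest-mapq copy,
    ties broken by lexicographically smallest name; output preserves the
    input order of the representatives' groups.
    """
    anchors = sorted(v.pos for v in variants if not v.is_indel)
    best: dict = {}
    order: List[tuple] = []
    for read in reads:
        key = _dedup_key(read, anchors)
        kept = best.get(key)
        if kept is None:
            best[key] = read
            order.append(key)
        elif (-read.mapq, read.name) < (-kept.mapq, kept.name):
            best[key] = read
    retained = [best[k] for k in order]
    return retained, len(reads) - len(retained)


# ---------------------------------------------------------------------------
# per-read assignment


def _call(read, variant, assay, call, reason) -> AlleleCall:
    return AlleleCall(read.name, variant.id, assay, call, reason)


def _assign_snv_base(read: AlignedRead, variant: VariantSpec, assay: str) -> AlleleCall:
    b = base_at(read, variant.pos)
    if b is None:
        return _call(read, variant, assay, "unassigned", "no_overlap")
    if b == variant.ref_allele:
        return _call(read, variant, assay, "wildtype", "snv_base")
    if b == variant.alt_allele:
        return _call(read, variant, assay, "mutant", "snv_base")
    return _call(read, variant, assay, "unassigned", "third_allele")


def _assign_dup_window(read: AlignedRead, variant: VariantSpec, assay: str) -> AlleleCall:
    wt = variant.wildtype_window()
    mut = variant.mutant_window()
    has_wt = wt in read.bases
    has_mut = mut in read.bases
    # guard against degenerate flanks making both windows match
    if has_wt and has_mut:
        return _call(read, variant, assay, "unassigned", "third_allele")
    if has_mut:
        return _call(read, variant, assay, "mutant", "flank_match")
    if has_wt:
        return _call(read, variant, assay, "wildtype", "flank_match")
    # distinguish "never saw the site" from "saw it but mismatched"
    window_lo, window_hi = variant.pos - 10, variant.pos + 10
    covers = any(s <= window_lo and window_hi <= e for s, e in ref_blocks(read))
    reason = "third_allele" if covers else "no_overlap"
    return _call(read, variant, assay, "unassigned", reason)


def assign_chip(
    read: AlignedRead,
    variant: VariantSpec,
    min_aligned_frac: Optional[float] = 0.9,
) -> AlleleCall:
    """Assign a ChIP-seq (genomic) read to an allele.

    Genomic DNA carries no splicing, so only sequence-level rules apply:
    the variant base for SNV-like classes, the exact flanked sequence
    window for the duplication. Reads failing the aligned-fraction gate
    (strictly more than ``min_aligned_frac`` of bases aligned is required)
    are unassigned.
    """
    if read.chrom != variant.chrom:
        return _call(read, variant, "chip", "unassigned", "no_overlap")
    if min_aligned_frac is not None and aligned_fraction(read) <= min_aligned_frac:
        return _call(read, variant, "chip", "unassigned", "aligned_fraction_fail")
    if variant.var_class == "duplication":
        return _assign_dup_window(read, variant, "chip")
    return _assign_snv_base(read, variant, "chip")


def assign_rna(
    read: AlignedRead,
    variant: VariantSpec,
    min_aligned_frac: Optional[float] = None,
) -> AlleleCall:
    """Assign an RNA-seq read to an allele, honouring splice patterns.

    The aligned-fraction gate is off by default for RNA (it is stated for
    ChIP reads only); pass ``min_aligned_frac=0.9`` to apply it here too.
    """
    if read.chrom != variant.chrom:
        return _call(read, variant, "rna", "unassigned", "no_overlap")
    if min_aligned_frac is not None and aligned_fraction(read) <= min_aligned_frac:
        return _call(read, variant, "rna", "unassigned", "aligned_fraction_fail")

    if variant.var_class == "snv":
        return _assign_snv_base(read, variant, "rna")

    intron = variant.affected_intron
    skips = skip_blocks(read)

    if variant.var_class == "duplication":
        # correct donor AND acceptor -> wildtype; exactly one -> mutant
        for s, e in skips:
            if (s, e) == intron:
                return _call(read, variant, "rna", "wildtype", "junction_spliced")
        for s, e in skips:
            if (s == intron[0]) != (e == intron[1]):
                return _call(read, variant, "rna", "mutant", "one_sided_splice")
        return _call(read, variant, "rna", "unassigned", "no_overlap")

    # splice_acceptor_snv
    for s, e in skips:
        if (s, e) == intron:
            return _call(read, variant, "rna", "wildtype", "junction_spliced")
    runs_through = spans_continuously(read, intron[1], variant.downstream_exon_start)
    if runs_through:
        b = base_at(read, variant.pos)
        if b == variant.ref_allele:
            return _call(read, variant, "rna", "wildtype", "intron_runthrough_base")
        if b == variant.alt_allele:
            return _call(read, variant, "rna", "mutant", "intron_runthrough_base")
        if b is not None:
            return _call(read, variant, "rna", "unassigned", "third_allele")
    return _call(read, variant, "rna", "unassigned", "no_overlap")


def assign(read, variant, assay, min_aligned_frac="default"):
    """Dispatch to the per-assay rule with its default gate."""
    if assay == "chip":
        frac = 0.9 if min_aligned_frac == "default" else min_aligned_frac
        return assign_chip(read, variant, frac)
    if assay == "rna":
        frac = None if min_aligned_frac == "default" else min_aligned_frac
        return assign_rna(read, variant, frac)
    raise ValueError(f"unknown assay {assay!r}")


# ---------------------------------------------------------------------------
# locus-level quantification


def quantify_locus(
    reads: Sequence[AlignedRead],
    variant: VariantSpec,
    assay: str,
    dedup_variants: Optional[Iterable[VariantSpec]] = None,
    min_aligned_frac="default",
    dedup: bool = True,
) -> Tuple[AlleleCounts, List[AlleleCall]]:
    """Deduplicate, assign every retained read, and tally.

    ``dedup_variants`` supplies the non-indel anchor variants used for the
    duplicate identity; it defaults to the variant being quantified (with
    indel-class variants contributing no base anchor).
    ``dedup=False`` skips duplicate removal — appropriate for simulation
    studies of the classification rules at saturating locus depth, where
    the duplicate identity (same interval, same variant-site bases) cannot
    distinguish distinct molecules that happen to share an alignment.
    Returns the counts plus the full per-read call list for audit.
    """
    if assay not in ("chip", "rna"):
        raise ValueError(f"unknown assay {assay!r}")
    if dedup:
        anchors = list(dedup_variants) if dedup_variants is not None else [variant]
        retained, n_removed = deduplicate(reads, anchors)
    else:
        retained, n_removed = list(reads), 0
    counts = AlleleCounts(variant.id, assay, n_duplicates_removed=n_removed)
    calls = []
    for read in retained:
        c = assign(read, variant, assay, min_aligned_frac)
        calls.append(c)
        if c.call == "wildtype":
            counts.n_wildtype += 1
        elif c.call == "mutant":
            counts.n_mutant += 1
        else:
            counts.n_unassigned += 1
    return counts, calls
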