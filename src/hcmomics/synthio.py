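"""Synthetic inputs with known ground truth for every downstream stage.

Two families of generators live here:

* ``simulate_locus_reads`` emits pre-aligned 75 bp single-end reads drawn
  from the wildtype or mutant haplotype of a synthetic locus, honouring the
  splice behaviour of each variant class (intron retention for the broken
  acceptor, one-sided donor/acceptor usage for the duplication), with
  optional PCR duplicates and base errors. Reads are emitted over a locus
  whose geometry mirrors the *MYBPC3* situations the classifier handles;
  every read is drawn so that it covers the informative site for its
  variant class, i.e. the simulator emulates the subset of a library that
  an allele-specific analysis would actually interrogate.

* ``simulate_multiomics`` draws a pair of samples-by-features count
  matrices (regions and genes) from an overdispersed (gamma-Poisson)
  count model whose log-mean carries a shared latent factor correlated
  with the case/control label plus additive planted differential effects.
  ``simulate_differential_tables`` fabricates the DESeq2-style summary
  tables consumed downstream, and ``simulate_concordance_study`` wires
  everything into a full synthetic study with a known concordant gene set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .reads import AlignedRead
from .variants import LocusTemplate, VariantSpec

_BASES = "ACGT"
_LN2 = math.log(2.0)

# ---------------------------------------------------------------------------
# locus templates


def make_locus_template(var_class: str, seed: int = 0, reference_name: Optional[str] = None) -> LocusTemplate:
    """A default synthetic locus for one variant class.

    Geometry: exon 1 = [1, 400], intron = [401, 700], exon 2 = [701, 1100]
    (an analogue of the *MYBPC3* intron 11 or intron 23 neighbourhood).
    The wildtype sequence is random but pinned at the functional sites:
    canonical GT donor and AG acceptor dinucleotides, and bases around the
    duplication chosen so the wildtype and mutant sequence windows cannot
    both match one read.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(_BASES), size=1100))
    exons = ((1, 400), (701, 1100))
    intron = (401, 700)
    name = reference_name or f"synth_{var_class}"

    # canonical splice sites
    seq[400], seq[401] = "G", "T"      # donor GT at intron start
    seq[698], seq[699] = "A", "G"      # acceptor AG at intron end

    if var_class == "snv":
        pos = 200
        seq[pos - 1] = "C"
        variant = VariantSpec(
            id="rsSNV", cdna_name="c.synthC>T", var_class="snv",
            chrom=name, pos=pos, ref_allele="C", alt_allele="T",
        )
    elif var_class == "splice_acceptor_snv":
        pos = 699  # the A of the AG acceptor, two bases before exon 2
        variant = VariantSpec(
            id="rsACC", cdna_name="c.synth-2A>G", var_class="splice_acceptor_snv",
            chrom=name, pos=pos, ref_allele="A", alt_allele="G",
            intron_start=401, intron_end=700, downstream_exon_start=701,
        )
    elif var_class == "duplication":
        pos = 401  # the duplicated base is the G of the donor
        seq[399] = "C"  # last exon-1 base != G, keeps the windows unambiguous
        flank_left = "".join(seq[390:400])
        flank_right = "".join(seq[401:411])
        variant = VariantSpec(
            id="rsDUP", cdna_name="c.synthdupG", var_class="duplication",
            chrom=name, pos=pos, ref_allele="G", alt_allele="GG",
            flank_left=flank_left, flank_right=flank_right,
            intron_start=401, intron_end=700,
        )
    else:
        raise ValueError(f"unknown variant class {var_class!r}")

    return LocusTemplate(
        reference_name=name,
        exon_blocks=exons,
        intron_blocks=(intron,),
        wildtype_sequence="".join(seq),
        variant=variant,
    )


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimTruth:
    """Ground truth for a simulated read batch."""

    mutant_fraction: float
    seed: int
    origins: Dict[str, str] = field(default_factory=dict)      # every emitted read
    dup_group: Dict[str, int] = field(default_factory=dict)
    n_wildtype: int = 0   # template (distinct-molecule) counts; sum == depth
    n_mutant: int = 0


def _spliced_read(template, name, overhang, intron, tail_start, read_length, mutant_tag, dup_group):
    """A junction read: ``overhang`` exonic bases, a skip, then the rest."""
    start = intron[0] - overhang
    up = template.slice(start, intron[0] - 1)
    down_len = read_length - overhang
    down = template.slice(tail_start, tail_start + down_len - 1)
    skip_len = tail_start - intron[0]
    cigar = (("M", overhang), ("N", skip_len), ("M", down_len))
    return AlignedRead(name, template.reference_name, start, cigar, up + down,
                       tags={"XO": mutant_tag, "XD": dup_group})


def _make_read(template: LocusTemplate, assay: str, origin: str, name: str,
               read_length: int, rng, aberrant_offset: int, dup_group: int) -> AlignedRead:
    v = template.variant
    pos = v.pos
    lo, hi = template.locus_start, template.locus_end
    mut_seq = template.mutant_sequence()
    tags = {"XO": origin, "XD": dup_group}

    def hap_slice(start, end):
        # contiguous genomic haplotype bases; valid only upstream of (or not
        # crossing) the duplication insertion point for the mutant haplotype
        if origin == "wildtype":
            return template.slice(start, end)
        if v.var_class == "duplication":
            raise AssertionError("mutant duplication reads are built explicitly")
        return mut_seq[start - template.offset : end - template.offset + 1]

    if assay == "chip":
        if v.var_class == "duplication":
            if origin == "wildtype":
                # full 21-base window must sit inside the read
                s = int(rng.integers(max(lo, pos + 10 - read_length + 1), pos - 10 + 1))
                return AlignedRead(name, template.reference_name, s, (("M", read_length),),
                                   template.slice(s, s + read_length - 1), tags=tags)
            # mutant: matched run to pos, 1-base insertion (the extra copy), rest matched
            a = int(rng.integers(11, read_length - 10))  # bases up to and incl. pos
            s = pos - a + 1
            b = read_length - 1 - a
            bases = template.slice(s, pos) + v.ref_allele + template.slice(pos + 1, pos + b)
            cigar = (("M", a), ("I", 1), ("M", b))
            return AlignedRead(name, template.reference_name, s, cigar, bases, tags=tags)
        # SNV-like: any genomic read covering the variant position
        s = int(rng.integers(max(lo, pos - read_length + 1), min(pos, hi - read_length + 1) + 1))
        return AlignedRead(name, template.reference_name, s, (("M", read_length),),
                           hap_slice(s, s + read_length - 1), tags=tags)

    # RNA
    intron = v.affected_intron
    if v.var_class == "snv":
        exon = next(b for b in template.exon_blocks if b[0] <= pos <= b[1])
        s = int(rng.integers(max(exon[0], pos - read_length + 1), min(pos, exon[1] - read_length + 1) + 1))
        return AlignedRead(name, template.reference_name, s, (("M", read_length),),
                           hap_slice(s, s + read_length - 1), tags=tags)

    if origin == "wildtype":
        # correctly spliced junction read: skip exactly the affected intron
        a = int(rng.integers(1, read_length))
        return _spliced_read(template, name, a, intron, intron[1] + 1, read_length,
                             origin, dup_group)

    if v.var_class == "splice_acceptor_snv":
        # intron retention: gapless read through the intron/exon boundary,
        # covering the variant position (which carries the alternate base)
        s = int(rng.integers(intron[1] + 2 - read_length, pos + 1))
        return AlignedRead(name, template.reference_name, s, (("M", read_length),),
                           hap_slice(s, s + read_length - 1), tags=tags)

    # duplication, mutant: spliced at exactly one correct coordinate
    a = int(rng.integers(1, read_length))
    if rng.random() < 0.5:
        # correct donor, aberrant acceptor shifted into exon 2
        return _spliced_read(template, name, a, intron,
                             intron[1] + 1 + aberrant_offset, read_length, origin, dup_group)
    # aberrant donor inside exon 1, correct acceptor
    shifted = (intron[0] - aberrant_offset, intron[1])
    return _spliced_read(template, name, a, shifted, intron[1] + 1, read_length,
                         origin, dup_group)


def _apply_errors(read: AlignedRead, error_rate: float, rng) -> AlignedRead:
    n = rng.binomial(len(read.bases), error_rate)
    if n == 0:
        return read
    bases = list(read.bases)
    for i in rng.choice(len(bases), size=n, replace=False):
        bases[i] = rng.choice([b for b in _BASES if b != bases[i]])
    return AlignedRead(read.name, read.chrom, read.start, read.cigar,
                       "".join(bases), read.mapq, dict(read.tags))


def simulate_locus_reads(
    template: LocusTemplate,
    assay: str,
    mutant_fraction: float,
    depth: int,
    read_length: int = 75,
    error_rate: float = 0.0,
    duplicate_rate: float = 0.0,
    seed: int = 0,
    aberrant_offset: int = 24,
    perturb_duplicates: bool = False,
) -> Tuple[List[AlignedRead], SimTruth]:
    """Simulate aligned single-end reads over the locus with known origin.

    ``depth`` counts distinct molecules (duplicate groups); PCR duplicates
    are appended as exact copies, each template gaining extra copies with
    geometric tail probability ``duplicate_rate``. With ``error_rate`` 0
    every read's bases match its haplotype exactly. ``aberrant_offset``
    sets how far (bases) the mutant duplication allele's cryptic splice
    site lies from the correct one. ``perturb_duplicates`` flips one base
    of each copy at a position away from the variant site, to exercise the
    "identical bases at the variant positions" clause of deduplication.
    """
    if not 0.0 <= mutant_fraction <= 1.0:
        raise ValueError("mutant_fraction must be within [0, 1]")
    if assay not in ("chip", "rna"):
        raise ValueError(f"unknown assay {assay!r}")
    if read_length > template.span:
        raise ValueError("read_length exceeds the locus span")
    truth = SimTruth(mutant_fraction=mutant_fraction, seed=seed)
    if depth == 0:
        warnings.warn("depth=0: returning an empty read set", stacklevel=2)
        return [], truth

    rng = np.random.default_rng(seed)
    origins = np.where(rng.random(depth) < mutant_fraction, "mutant", "wildtype")
    reads: List[AlignedRead] = []
    anchor = None if template.variant.is_indel else template.variant.pos

    for i, origin in enumerate(origins):
        name = f"r{i:06d}"
        read = _make_read(template, assay, str(origin), name, read_length, rng,
                          aberrant_offset, dup_group=i)
        if error_rate > 0:
            read = _apply_errors(read, error_rate, rng)
        reads.append(read)
        truth.origins[name] = str(origin)
        truth.dup_group[name] = i
        if origin == "mutant":
            truth.n_mutant += 1
        else:
            truth.n_wildtype += 1
        n_extra = (rng.geometric(1.0 - duplicate_rate) - 1) if duplicate_rate > 0 else 0
        for j in range(n_extra):
            dup_name = f"{name}_dup{j}"
            bases = read.bases
            if perturb_duplicates:
                bases = _perturb_away_from(read, anchor, rng)
            dup = AlignedRead(dup_name, read.chrom, read.start, read.cigar, bases,
                              read.mapq, {"XO": str(origin), "XD": i})
            reads.append(dup)
            truth.origins[dup_name] = str(origin)
            truth.dup_group[dup_name] = i
    return reads, truth


def _perturb_away_from(read: AlignedRead, anchor: Optional[int], rng) -> str:
    """Flip one read base not aligned to the anchor variant position."""
    from .reads import base_at  # local import to avoid cycle at module load

    bases = list(read.bases)
    for _ in range(50):
        i = int(rng.integers(len(bases)))
        if anchor is not None:
            # walk to the reference position of query index i
            ref, q = read.start, 0
            hit = None
            for op, ln in read.cigar:
                if op == "M":
                    if q <= i < q + ln:
                        hit = ref + (i - q)
                    ref += ln
                    q += ln
                elif op in ("I", "S"):
                    if q <= i < q + ln:
                        hit = None
                    q += ln
                else:
                    ref += ln
            if hit == anchor:
                continue
        bases[i] = str(rng.choice([b for b in _BASES if b != bases[i]]))
        return "".join(bases)
    return "".join(bases)


# ---------------------------------------------------------------------------
# paired omics matrices


@dataclass
class OmicsSimTruth:
    """Ground truth for a simulated two-omics study."""

    sample_ids: List[str]
    group_labels: List[str]                  # 'control' / 'case' per sample
    factor_scores: pd.DataFrame              # samples x joint_rank
    loadings_x: pd.DataFrame                 # regions x joint_rank, unit-norm cols
    loadings_y: pd.DataFrame                 # genes x joint_rank, unit-norm cols
    de_x_up: List[str]
    de_x_down: List[str]
    de_y_up: List[str]
    de_y_down: List[str]
    de_effect: float                         # natural-log half-difference per group
    dispersion: float
    group_effect: float
    seed: int

    @property
    def group_signs(self) -> np.ndarray:
        return np.array([1.0 if g == "case" else -1.0 for g in self.group_labels])

    def de_sign(self, side: str, feature: str) -> int:
        up = self.de_y_up if side == "Y" else self.de_x_up
        down = self.de_y_down if side == "Y" else self.de_x_down
        if feature in up:
            return 1
        if feature in down:
            return -1
        return 0


def _unit_norm_loadings(rng, n_features: int, rank: int, ids,
                        up_features=(), down_features=(), boost: float = 1.0) -> pd.DataFrame:
    w = rng.normal(size=(n_features, rank))
    if boost != 1.0:
        # inflate planted DE features on the group factor and orient their
        # loading sign with the DE direction so both signals reinforce
        up = set(up_features)
        down = set(down_features)
        # the magnitude floor keeps boosted features separated from the
        # background |N(0,1)| draws rather than merely rescaled
        for i, f in enumerate(ids):
            if f in up:
                w[i, 0] = boost * max(abs(w[i, 0]), 1.0)
            elif f in down:
                w[i, 0] = -boost * max(abs(w[i, 0]), 1.0)
    w /= np.linalg.norm(w, axis=0, keepdims=True)
    return pd.DataFrame(w, index=ids, columns=[f"joint{k + 1}" for k in range(rank)])


def _pick_de(rng, ids, n_de: int) -> Tuple[List[str], List[str]]:
    chosen = rng.choice(len(ids), size=n_de, replace=False)
    n_up = n_de // 2
    up = sorted(ids[i] for i in chosen[:n_up])
    down = sorted(ids[i] for i in chosen[n_up:])
    return up, down


def simulate_multiomics(
    n_samples: int = 23,
    p_regions: int = 2000,
    q_genes: int = 1000,
    joint_rank: int = 1,
    group_effect: float = 2.0,
    dispersion: float = 0.3,
    n_de: int = 100,
    seed: int = 0,
    group_sizes: Optional[Tuple[int, int]] = None,
    factor_scale: float = 0.15,
    factor_noise_sd: float = 0.3,
    de_effect: float = 0.7,
    baseline_log_mean: float = math.log(100.0),
    baseline_log_sd: float = 1.0,
    de_features: Optional[dict] = None,
    de_loading_boost: float = 1.0,
) -> Tuple[pd.DataFrame, pd.DataFrame, OmicsSimTruth]:
    """Two-group count matrices with a planted joint factor and DE features.

    The default shapes (23 samples, regions and genes in the thousands)
    are a desk-scale rendition of a 23-sample two-omics cardiac study
    (23 x 33,642 regions and 23 x 15,882 genes at full scale). The
    log-mean of feature *j* in sample *i* is::

        b_j + sqrt(p) * factor_scale * sum_k t_ik w_jk + 0.5 * d_j * g_i

    with ``t_1`` the group-separating factor (mean +/- group_effect/2 per
    group, within-group sd ``factor_noise_sd``), ``w`` unit-norm loading
    columns, ``d_j`` the signed DE effect (natural log) on planted
    features, and ``g_i`` the group sign. Counts are gamma-Poisson with
    common dispersion (var = mu + dispersion * mu^2).

    ``de_features`` may pin the planted sets explicitly:
    ``{"x_up": [...], "x_down": [...], "y_up": [...], "y_down": [...]}``.
    ``de_loading_boost`` inflates the joint-loading magnitude of planted
    gene/region DE features (used by the study-level generator so that DE
    genes also rank high on the joint component).
    """
    if joint_rank < 1:
        raise ValueError("joint_rank must be >= 1")
    if n_de > min(p_regions, q_genes):
        raise ValueError("n_de exceeds the feature universe")
    if group_sizes is None:
        if n_samples % 2:
            raise ValueError("n_samples must be even unless group_sizes is given")
        group_sizes = (n_samples // 2, n_samples - n_samples // 2)
    elif sum(group_sizes) != n_samples:
        raise ValueError("group_sizes must sum to n_samples")

    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    labels = ["control"] * group_sizes[0] + ["case"] * group_sizes[1]
    g = np.array([1.0 if x == "case" else -1.0 for x in labels])

    region_ids = [f"R{j + 1:05d}" for j in range(p_regions)]
    gene_ids = [f"G{j + 1:05d}" for j in range(q_genes)]

    if de_features is None:
        x_up, x_down = _pick_de(rng, region_ids, n_de)
        y_up, y_down = _pick_de(rng, gene_ids, n_de)
    else:
        x_up = sorted(de_features.get("x_up", []))
        x_down = sorted(de_features.get("x_down", []))
        y_up = sorted(de_features.get("y_up", []))
        y_down = sorted(de_features.get("y_down", []))

    t = rng.normal(scale=1.0, size=(n_samples, joint_rank))
    t[:, 0] = 0.5 * group_effect * g + rng.normal(scale=factor_noise_sd, size=n_samples)

    w_x = _unit_norm_loadings(rng, p_regions, joint_rank, region_ids,
                              x_up, x_down, de_loading_boost)
    w_y = _unit_norm_loadings(rng, q_genes, joint_rank, gene_ids,
                              y_up, y_down, de_loading_boost)

    def _counts(ids, w, up, down, p):
        b = rng.normal(baseline_log_mean, baseline_log_sd, size=p)
        d = np.zeros(p)
        idx = {f: i for i, f in enumerate(ids)}
        for f in up:
            d[idx[f]] = de_effect
        for f in down:
            d[idx[f]] = -de_effect
        log_mu = b[None, :] + math.sqrt(p) * factor_scale * (t @ w.to_numpy().T) \
            + 0.5 * np.outer(g, d)
        mu = np.exp(np.clip(log_mu, None, 20.0))
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        else:
            lam = mu
        return rng.poisson(lam).astype(np.int64)

    X = pd.DataFrame(_counts(region_ids, w_x, x_up, x_down, p_regions),
                     index=sample_ids, columns=region_ids)
    Y = pd.DataFrame(_counts(gene_ids, w_y, y_up, y_down, q_genes),
                     index=sample_ids, columns=gene_ids)

    truth = OmicsSimTruth(
        sample_ids=sample_ids, group_labels=labels,
        factor_scores=pd.DataFrame(t, index=sample_ids,
                                   columns=[f"joint{k + 1}" for k in range(joint_rank)]),
        loadings_x=w_x, loadings_y=w_y,
        de_x_up=x_up, de_x_down=x_down, de_y_up=y_up, de_y_down=y_down,
        de_effect=de_effect, dispersion=dispersion, group_effect=group_effect,
        seed=seed,
    )
    return X, Y, truth


# ---------------------------------------------------------------------------
# fabricated differential tables (stand-ins for DESeq2 outputs)

TSS_SPACING = 100_000
REGION_WIDTH = 1_000


def synthetic_tss_table(gene_ids: Sequence[str], chrom: str = "chrS") -> pd.DataFrame:
    """Deterministic TSS layout: gene *j* at ``TSS_SPACING * (j+1)``, 1-based."""
    rows = [
        {"gene": gid, "chrom": chrom, "tss": TSS_SPACING * (j + 1),
         "strand": "+" if j % 2 == 0 else "-"}
        for j, gid in enumerate(gene_ids)
    ]
    return pd.DataFrame(rows)


def _de_table(rng, ids, up, down, alpha, de_effect, sign_scale=0.5, null_sd=0.15) -> pd.DataFrame:
    rows = []
    up, down = set(up), set(down)
    for f in ids:
        if f in up or f in down:
            sign = 1.0 if f in up else -1.0
            lfc = sign * (de_effect / _LN2 + sign_scale * rng.random())
            padj = float(rng.uniform(1e-12, alpha * 0.999))
        else:
            lfc = float(rng.normal(0.0, null_sd))
            padj = float(rng.uniform(alpha, 1.0))
        rows.append({"feature": f, "log2fc": float(lfc), "padj": padj})
    return pd.DataFrame(rows)


def simulate_differential_tables(
    truth: OmicsSimTruth,
    alpha: float = 0.05,
    gene_ids: Optional[Sequence[str]] = None,
    region_ids: Optional[Sequence[str]] = None,
    region_offsets: Optional[Dict[str, Tuple[str, int]]] = None,
    chrom: str = "chrS",
) -> Dict[str, pd.DataFrame]:
    """Fabricate RNA / protein DE tables and an acetylome region table.

    Planted DE features receive adjusted p below ``alpha`` with the planted
    sign; every other feature draws p uniformly from (alpha, 1]. Region
    coordinates are laid out on a synthetic chromosome: by default region
    *j* sits 2.5 kb upstream of gene *j*'s TSS (within the 5 kb annotation
    window) while surplus regions land in gene deserts. ``region_offsets``
    overrides placement per region id with ``(gene_id, signed offset from
    that gene's TSS)``.
    """
    rng = np.random.default_rng(truth.seed + 104729)  # independent stream
    gene_ids = list(gene_ids) if gene_ids is not None else list(truth.loadings_y.index)
    region_ids = list(region_ids) if region_ids is not None else list(truth.loadings_x.index)

    rna = _de_table(rng, gene_ids, truth.de_y_up, truth.de_y_down, alpha, truth.de_effect)
    protein = _de_table(rng, gene_ids, truth.de_y_up, truth.de_y_down, alpha,
                        0.6 * truth.de_effect, sign_scale=0.3)

    tss = synthetic_tss_table(gene_ids, chrom=chrom)
    tss_of = dict(zip(tss["gene"], tss["tss"]))
    acet = _de_table(rng, region_ids, truth.de_x_up, truth.de_x_down, alpha, truth.de_effect)

    desert = TSS_SPACING * (len(gene_ids) + 2)
    starts = []
    for j, rid in enumerate(region_ids):
        if region_offsets is not None and rid in region_offsets:
            gene, off = region_offsets[rid]
            start = tss_of[gene] + off
        elif j < len(gene_ids):
            start = tss_of[gene_ids[j]] - 2500
        else:
            start = desert + REGION_WIDTH * 3 * (j - len(gene_ids) + 1)
        starts.append(int(start))
    acet.insert(0, "chrom", chrom)
    acet.insert(1, "start", starts)                       # 0-based half-open
    acet.insert(2, "end", [s + REGION_WIDTH for s in starts])
    return {"rna": rna, "protein": protein, "acetylome_regions": acet, "tss": tss}


# ---------------------------------------------------------------------------
# full synthetic study with a planted concordance pattern


@dataclass
class ConcordanceStudy:
    """A complete synthetic two-omics study plus the planted expectations.

    ``tables`` holds the fabricated inputs consumed downstream (rna,
    protein, acetylome_regions, tss, plasma); ``expected`` records the
    gene sets the pipeline should recover: ``up``/``down`` (ranked genes
    intersected with RNA DE), ``protein_up``/``protein_down`` (proteome
    sign-and-significance concordant), ``discordant``, and
    ``fully_concordant_5kb``/``fully_concordant_50kb``.
    """

    X: pd.DataFrame
    Y: pd.DataFrame
    groups: List[str]
    truth: OmicsSimTruth
    tables: Dict[str, pd.DataFrame]
    top_k: int
    alpha: float
    expected: Dict[str, object]


#: per-direction role multiset for planted DE genes: protein-concordant with a
#: matching DAR within 5 kb / only within 50 kb, concordant without any DAR,
#: concordant with an opposite-direction DAR, protein-discordant, protein
#: non-significant
_ROLES = (
    ["dar_5kb"] * 6 + ["dar_50kb"] * 4 + ["dar_wrong"] * 3
    + ["no_dar"] * 3 + ["prot_discordant"] * 2 + ["prot_nonsig"] * 2
)


def simulate_concordance_study(
    seed: int = 0,
    group_sizes: Tuple[int, int] = (10, 13),
    p_regions: int = 400,
    q_genes: int = 400,
    group_effect: float = 2.0,
    dispersion: float = 0.3,
    top_k: int = 150,
    alpha: float = 0.05,
) -> ConcordanceStudy:
    """Simulate count matrices plus all downstream tables with known truth.

    40 genes (20 per direction) are planted as RNA-differential and given
    inflated joint loadings so they rank inside the top ``top_k`` of the
    joint component; each receives one of six concordance roles (see
    ``_ROLES``) controlling its protein behaviour, DAR placement and
    plasma detectability. Everything needed by the full pipeline run is
    returned together with the exact gene sets each stage should recover.
    """
    rng = np.random.default_rng(seed)
    n_de_dir = len(_ROLES)
    n_de = 2 * n_de_dir
    if n_de > min(p_regions, q_genes) or n_de + 2 > q_genes:
        raise ValueError("feature universe too small for the planted design")

    gene_ids = [f"G{j + 1:05d}" for j in range(q_genes)]
    region_ids = [f"R{j + 1:05d}" for j in range(p_regions)]
    de_genes = sorted(rng.choice(gene_ids, size=n_de, replace=False))
    up_genes, down_genes = de_genes[:n_de_dir], de_genes[n_de_dir:]

    roles = {}
    for genes in (up_genes, down_genes):
        order = list(rng.permutation(_ROLES))
        roles.update(dict(zip(genes, order)))

    # one reserved region per DE gene that needs a (significant) DAR
    offsets = {"dar_5kb": -2_000, "dar_50kb": -35_000, "dar_wrong": -2_500}
    region_offsets: Dict[str, Tuple[str, int]] = {}
    x_up, x_down = [], []
    pool = iter(region_ids)
    for gene in de_genes:
        role = roles[gene]
        if role not in offsets:
            continue
        rid = next(pool)
        region_offsets[rid] = (gene, offsets[role])
        rna_sign = 1 if gene in up_genes else -1
        dar_sign = -rna_sign if role == "dar_wrong" else rna_sign
        (x_up if dar_sign > 0 else x_down).append(rid)

    X, Y, truth = simulate_multiomics(
        n_samples=sum(group_sizes), p_regions=p_regions, q_genes=q_genes,
        joint_rank=1, group_effect=group_effect, dispersion=dispersion,
        n_de=n_de, seed=seed, group_sizes=group_sizes,
        baseline_log_mean=math.log(200.0), baseline_log_sd=0.8,
        de_features={"x_up": x_up, "x_down": x_down,
                     "y_up": up_genes, "y_down": down_genes},
        de_loading_boost=8.0,
    )

    tables = simulate_differential_tables(
        truth, alpha=alpha, gene_ids=gene_ids, region_ids=region_ids,
        region_offsets=region_offsets,
    )

    # overwrite the protein table so each role behaves as planted
    trng = np.random.default_rng(seed + 15485863)
    prot_rows = []
    for g in gene_ids:
        role = roles.get(g)
        rna_sign = 1.0 if g in set(up_genes) else (-1.0 if g in set(down_genes) else 0.0)
        if role in ("dar_5kb", "dar_50kb", "dar_wrong", "no_dar"):
            lfc = rna_sign * (0.4 + 0.6 * trng.random())
            padj = float(trng.uniform(1e-10, alpha * 0.99))
        elif role == "prot_discordant":
            lfc = -rna_sign * (0.4 + 0.6 * trng.random())
            padj = float(trng.uniform(1e-10, alpha * 0.99))
        elif role == "prot_nonsig":
            lfc = rna_sign * 0.3 * trng.random()
            padj = float(trng.uniform(alpha + 0.01, 1.0))
        else:
            lfc = float(trng.normal(0.0, 0.15))
            padj = float(trng.uniform(alpha, 1.0))
        prot_rows.append({"feature": g, "log2fc": float(lfc), "padj": padj})
    tables["protein"] = pd.DataFrame(prot_rows)

    plasma_status = {}
    for g in gene_ids:
        role = roles.get(g)
        if role in ("dar_5kb", "dar_50kb", "dar_wrong"):
            plasma_status[g] = "detected"
        elif role in ("no_dar", "prot_discordant", "prot_nonsig"):
            plasma_status[g] = "not_detected"
        else:
            plasma_status[g] = str(trng.choice(["detected", "not_detected", "no_data"]))
    tables["plasma"] = pd.DataFrame(
        {"gene": gene_ids, "status": [plasma_status[g] for g in gene_ids]}
    )

    concordant_roles = ("dar_5kb", "dar_50kb", "dar_wrong", "no_dar")
    expected = {
        "up": set(up_genes),
        "down": set(down_genes),
        "protein_up": {g for g in up_genes if roles[g] in concordant_roles},
        "protein_down": {g for g in down_genes if roles[g] in concordant_roles},
        "discordant": {g for g in de_genes if roles[g] == "prot_discordant"},
        "fully_concordant_5kb": {g for g in de_genes if roles[g] == "dar_5kb"},
        "fully_concordant_50kb": {g for g in de_genes
                                  if roles[g] in ("dar_5kb", "dar_50kb")},
        "plasma_detected_rows": sum(
            1 for g in de_genes if roles[g] in ("dar_5kb", "dar_50kb", "dar_wrong")
        ),
        "roles": roles,
    }
    return ConcordanceStudy(
        X=X, Y=Y, groups=list(truth.group_labels), truth=truth, tables=tables,
        top_k=top_k, alpha=alpha, expected=expected,
    )
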