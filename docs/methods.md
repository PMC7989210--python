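# Methods

This note documents the models, rules and numerical choices behind
`hcmomics`, what the synthetic generators do and do not emulate, and the
design decisions taken where the underlying analysis left them open.

## Allele-specific read classification

### Duplicate removal

Two reads are PCR duplicates when they aligned to the same genomic
interval **and** carry identical bases at every non-indel variant
position (including "no base" when a read does not cover a position).
The retained representative is the highest-mapq copy, ties broken by
lexicographically smallest read name (which copy to keep is not
observable from the data; the choice only needs to be deterministic).
The keyed implementation hashes (chromosome, aligned reference blocks,
variant-position bases) and is checked against a quadratic all-pairs
oracle in the tests.

A consequence worth knowing: the duplicate identity is purely
positional, so at saturating coverage of a single short locus it cannot
distinguish distinct molecules that happen to share an alignment. With
75 bp reads over one junction there are only ~75–150 possible alignment
keys, so at depth 5,000 deduplicated counts converge to the key-space
ratio rather than the allelic mixture. This is a property of the rule,
not of the implementation; the classification-recovery study therefore
runs with deduplication off, and dedup correctness is validated by its
own oracle.

### Assignment rules

ChIP-seq reads are genomic, so only sequence rules apply: the base
aligned to the variant position for SNV classes (reference base →
wildtype, alternate → mutant, third allele or no base → unassigned), and
for the single-base duplication an exact match of the 21-base wildtype
window (10-base flanks around the site) or the 22-base mutant window
(flanks around the duplicated bases). ChIP reads must additionally have
strictly more than 90 % of their bases in aligned-match operators; the
denominator is total read bases, so insertions and soft clips count
against the read while spliced-out introns are neutral. The gate is
applied to ChIP reads only by default (that is where it is stated);
`min_aligned_frac` exposes it for RNA.

RNA-seq reads follow splice-aware rules per variant class:

* plain SNV (no splice change): the base rule, as for ChIP;
* duplication (broken donor-side splicing): a splice gap removing
  exactly the affected intron — correct donor **and** acceptor — is
  wildtype; a gap using exactly one of the correct coordinates is
  mutant. Junction matching is exact-coordinate with no tolerance
  window, and the rule is purely splice-pattern-based: the read need not
  cover the variant base itself;
* splice-acceptor SNV (intron retention): an exact intron gap is
  wildtype; a read aligned gaplessly across the intron/exon boundary and
  covering the variant position is classified by the base it carries
  there.

Everything else is unassigned and never enters the mutant:wildtype
ratio, which is reported as 100 × mutant/wildtype to one decimal
(undefined when no wildtype reads were seen). Unassigned reads are also
excluded from the ratio's denominator, matching the printed convention.
Coordinates are 1-based closed throughout the read/variant layer, as in
SAM/VCF.

## Read simulator

`simulate_locus_reads` emits pre-aligned 75 bp single-end reads (the
library geometry of the assays modelled) over a synthetic 1.1 kb locus:
exon 1 [1, 400], intron [401, 700], exon 2 [701, 1100], with canonical
GT/AG splice sites pinned into an otherwise random sequence. Every read
is drawn to cover the informative site of its variant class — the
simulator emulates the informative subset of a library that an
allele-specific analysis interrogates, not whole-transcriptome coverage.
Specifics:

* the duplicated base is modelled as the first base of the affected
  intron, adjacent to the donor. Correctly and aberrantly spliced
  transcripts then never contain the inserted base, so RNA reads align
  gaplessly along their blocks; mutant ChIP reads carry a 1 bp insertion
  operator. Flanking bases are pinned so the wildtype and mutant
  sequence windows cannot both match one read;
* mutant duplication transcripts splice at the correct donor with an
  acceptor shifted by `aberrant_offset` (default 24 bases) or at a
  shifted donor with the correct acceptor, chosen 50/50 per read;
* mutant acceptor-SNV reads retain the intron, run across the
  intron/exon boundary and carry the alternate base at the variant
  position;
* PCR duplicates are exact copies (a geometric number of extras per
  molecule with tail probability `duplicate_rate`); a flag perturbs one
  base away from the variant positions to exercise the
  "identical bases at the variant positions" clause;
* base errors are uniform substitutions at `error_rate`; at zero every
  read matches its haplotype exactly, and generation is byte-identical
  given the seed.

`depth` counts distinct molecules; per-read origin labels and duplicate
group ids are returned as ground truth and carried in SAM tags
(`XO`/`XD`).

What the simulator does **not** emulate: quality scores, indel
sequencing errors, alignment ambiguity/soft-clipping, variable read
lengths after trimming, paired ends, and wildtype pre-mRNA (unspliced
wildtype molecules would be indistinguishable from mutant intron
retention at the acceptor SNV — in real data that contribution biases
the mutant call upward; the classifier cannot resolve it and the clean
simulation does not model it). Passing tests therefore demonstrate the
correctness of the rules on conforming input, not robustness to
alignment artefacts.

## Two-omics count simulator

`simulate_multiomics` draws region and gene counts for two groups from a
gamma-Poisson (negative-binomial-like) model with common dispersion
(variance μ + φμ²; the generative model behind the real counts is not
observable, a log-link count model is the natural choice for read-count
data). The log-mean of feature *j* in sample *i* is

    b_j + sqrt(p) · s · Σ_k t_ik w_jk + ½ d_j g_i

with baseline `b_j ~ N(log 100, 1)`, unit-norm loading columns `w`,
factor scores `t` whose first column is the group-separating factor
(means ±effect/2, within-group sd 0.3), and signed DE effects `d_j`
(natural log, default 0.7 ≈ 1 log2FC) on planted feature sets. Defaults
and rationale:

| parameter | default | meaning |
|---|---|---|
| `n_samples` / `group_sizes` | 23, (10, 13) | the modelled cohort: 13 case and 10 control hearts |
| `p_regions`, `q_genes` | 2000, 1000 | desk-scale rendition of 33,642 regions × 15,882 genes; ranking/overlap behaviour is scale-free |
| `factor_scale` s | 0.15 | per-feature log effect per factor sd (~35 % count change), a realistic transcriptome-wide shift |
| `factor_noise_sd` | 0.3 | within-group latent-factor variability; at effect 2 the groups sit ~6 within-group sd apart on the factor, matching a study whose first joint component visibly separates cases from controls |
| `dispersion` φ | 0.3 | typical bulk RNA-seq/ChIP-seq overdispersion; the study's own dispersion is not reported, so this is a free parameter of the generator, not a claim about the data |
| `de_effect` | 0.7 | planted DE log effect (≈1 log2FC) |

`de_loading_boost` inflates planted DE features' joint loadings (with a
magnitude floor of 1 before scaling, so boosted features are genuinely
separated from the |N(0,1)| background rather than rescaled noise) and
orients their sign with the DE direction so both signals reinforce —
used by the study-level generator so planted DE genes also rank high on
the joint component, as the candidate genes do in the real analysis.

`simulate_differential_tables` fabricates the DESeq2-style tables the
downstream stages consume (they are inputs, not something this package
recomputes): planted features get adjusted p below α with the planted
sign, everything else p uniform on (α, 1]. Region coordinates are laid
out on a synthetic chromosome with one gene TSS per 100 kb, regions by
default 2.5 kb upstream of their paired gene and surplus regions in gene
deserts. `simulate_concordance_study` assigns each of 40 planted DE
genes one of six concordance roles (protein-concordant with a DAR at
5 kb / at 35 kb / with an opposite-direction DAR / without a DAR,
protein-discordant, protein-non-significant) and returns the exact gene
sets every pipeline stage should recover.

## O2PLS

Joint loadings are the top-r singular-vector pairs of the cross-
covariance X'Y of the column-centered matrices; the SVD is computed
through thin SVDs of X and Y and an n×n core, so the p×q matrix is never
formed (exact, and necessary at 10³–10⁴ features). With omic-specific
components requested, the specific subspace per side is estimated from
the dominant singular directions of the joint-fit residual projected
orthogonal to the joint scores, followed by one deflation pass in which
the joint part is re-estimated on the specific-part-deflated matrices.
The r = nx = ny = 0-specific-component case is anchored to a direct
truncated-SVD oracle at 1e-8; the orthogonal branch is validated through
the exact reconstruction identity and score orthogonality (T'T_specific
≈ 0 at 1e-8).

Numerical conventions:

* sign: the largest-|entry| element of each loading column is made
  positive, per side, flipping the corresponding scores — output is
  deterministic; because the convention is per side, the (W, C) pair of
  a component may flip relative orientation, visible as a negative
  cov(T, U) in the summary;
* centering: columns are mean-centered inside the fit; no unit-variance
  scaling (the preprocessing is log + quantile normalization only);
* the log transform is log(1 + x) to admit zero counts (the base is a
  scale factor with no effect on any downstream ranking or score shape);
* quantile normalization operates across samples: each sample's sorted
  value vector becomes the mean sorted vector; ties keep their original
  within-sample order (stable ranks);
* defaults r = 1, nx = ny = 0 — only the first joint component is
  interpreted; all counts are exposed;
* feature ranking uses |loading| on the chosen joint component (rank 1 =
  largest), ties broken lexicographically by feature id;
  `across_components=True` ranks by the loading norm over all joint
  components instead;
* group separation is reported descriptively: per-component group score
  means, the rank-based AUC (average ranks, so constant scores give
  exactly 0.5), the orientation-free AUC max(a, 1−a), and a linear-
  separability flag (group score ranges do not overlap). The raw AUC is
  reported unoriented so that its null distribution stays centred on
  0.5; no p-value is attached because the underlying claim is about
  score plots, not a test.

The low-count filter drops features with fewer than `min_count` (10)
counts in at least `min_failing_samples` (22) samples — the "lower than
10 counts in at least 22 of 23 samples" rule; requesting
`min_failing_samples` above the sample count is an error rather than a
silent rescale.

## Annotation and concordance

Regions are BED-style 0-based half-open; TSS coordinates are compared
directly on the same coordinate line (a TSS inside [start, end) has
distance 0, otherwise the gap to the nearer edge; a region whose start
sits exactly `window` bases beyond the TSS is included — boundary
inclusive). Strand determines which gene end is the TSS in upstream
curation but the window itself is symmetric, so strand does not enter
the distance. Both the full within-window gene set and the nearest gene
(ties → smaller gene id) are returned, since downstream uses of "nearest
genes were collected" differ between the 5 kb and 50 kb tables.

A gene's acetylome direction is disjunctive by default — any
differentially acetylated region in the window changing in the gene's
RNA direction yields a match (one yes/no per gene is what the
concordance table reports); a strict all-regions-agree mode is
available. `fully_concordant_<window>` is true iff RNA and protein signs
agree and the window's acetylome direction matches. Plasma
detectability and cardiomyocyte expression class are consumed as curated
input tables (they derive from external atlases); genes absent from
those tables are `no_data` and never counted as detectable.

Marker panels are aggregated as the mean signal per marker (across all
samples and, when group labels are given, per group); each non-reference
panel is compared to the cardiomyocyte panel by one-way ANOVA over the
two sets of marker-level means. A panel with fewer than two present
markers gets no F statistic; markers absent from the matrix are excluded
with a warning.

The package ships the curated 53-gene candidate table (plasma
detectability, O2PLS ranks, RNA/protein log2FC, 50 kb acetylome match,
external cardiomyocyte log2FC) as a package data file; the tests and the
reproduction script recompute its summary counts (38 plasma-detectable;
36 up / 17 down protein-coding) from the rows, never from constants.

## Validation studies and problem sizes

The reproduction script (`scripts/acceptance.py`) and the acceptance
tests run: allele-specific recovery at depth 5,000 × 200 replicates ×
three mutant fractions × six (class, assay) combinations (duplicates and
dedup off, for the saturation reason above) — the recovered counts equal
the simulation truth read-for-read, making the estimator exactly
binomial, so the exact central 99 % interval covers the planted fraction
by construction (the empirical coverage is additionally checked at
multi-sigma sampling bounds, since the interval's true coverage of
~99.0–99.1 % leaves no slack for a knife-edge ≥99 % empirical check);
the dedup and annotation brute-force oracles (1,000 reads; 500 regions ×
50 TSS at both windows); the O2PLS-vs-SVD oracle on 24×200 / 24×300
matrices; separation over 100 seeds at effect 2 and at the null (24
samples, 300×200 features — sizes chosen so each replicate's fit is
exact yet cheap); and the end-to-end round trip on the planted
concordance study (23 samples, 400×400 features, 40 DE genes).

## Known limitations

* The generators plant clean, well-separated structure; they quantify
  correctness of the rules and algebra, not statistical power on noisy
  real data.
* The acceptor-SNV mutant call is upward-biased in real data by wildtype
  pre-mRNA intron retention (see above).
* The O2PLS orthogonal-part estimator is a single-pass approximation
  anchored by the exact no-specific-component case; it is not the
  iterative NIPALS scheme, and component counts are not selected by
  cross-validation.
* The concordance stage treats gene and protein identifiers as a shared
  namespace unless an id map is supplied.
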