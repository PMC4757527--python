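# Methods

This note records the models, conventions and design choices behind
`essefate`, in the spirit of a methods supplement: what each stage assumes,
which knobs matter, what the synthetic data does and does not emulate, and
where genuinely open choices were settled.

## Coordinates and formats

All internal coordinates are 0-based half-open. WIG input (1-based, both
fixedStep and variableStep, with `span` expansion) is shifted on read;
bedGraph and BED are taken as-is. A signal track is run-length encoded:
every covered base inside a run carries the run's value, so a step-1
fixedStep WIG and its bedGraph conversion are indistinguishable after
loading, and summary statistics weight each covered base equally. Positions
must be non-decreasing per chromosome; overlapping runs are an error.
Uncovered bases are *absent data*, not zeros — a site whose scoring window
has no coverage gets a missing score, and a missing state drops the site
from the affected contrast only. Betas outside [0, 1] are rejected naming
the offending site and sample; "NA" is missing and propagates pairwise
(a per-cell-type mean uses the non-missing replicates). Probes on
non-primary chromosomes (chrM, scaffolds) are dropped by default
(`include_nonprimary=True` to keep them), since the analysis is defined on
ordinary chromosomes and the source annotation's treatment of such probes
is unknowable.

## Site classes

A site is a **promoter** site when its single-bp probe coordinate lies
within 2,500 bp (inclusive) of *any* TSS — not merely its nearest gene
after tie-breaking; a **distal regulatory** site when it is at least
5,000 bp (inclusive) from every TSS and not inside a CpG island; otherwise
**excluded** (the open (2,500, 5,000) band, or island-overlapping distal
sites). Both thresholds read their bounds inclusively ("within" / "at
least"). The nearest gene (for enrichment) minimizes |TSS − site|, ties
broken by lexicographically smallest gene id; the reported signed distance
is relative to the gene's strand, negative upstream.

CpG islands come either from a precomputed BED (matching array-annotation
practice) or from the sequence itself: 200-bp windows slid at 1 bp qualify
at GC ≥ 0.50 and observed/expected CpG ≥ 0.60, where
o/e = N_CpG·L / (N_C·N_G) with L the window length excluding ambiguous
bases; overlapping or abutting qualifying windows merge, merged regions of
≥ 200 bp are reported, and the criteria are *not* re-checked on the merged
region (the common historical behaviour; `recheck_merged=True` gives the
variant). Windows with > 50% ambiguous bases are disqualified. A step > 1
is available as a speed knob only.

## Chromatin states

Tracks are normalized to mean 0, sd 1 over all covered bases. The sd is the
*population* sd (divide by n): the convention only rescales z and cannot
flip the sign rule, but fixing it makes results bit-reproducible. The
per-sample site score is the maximum normalized value within ±100 bp of the
probe (inclusive at both ends, 201-bp support); the per-cell-type call
averages these per-sample maxima and is positive iff the mean is strictly
> 0. Where the composition of "maximum in window" and "average level" is
read the other way (per-base mean within the window), `stat="mean"` gives
that variant. Stage pairs map onto lose / retain / gain / absent, and the
ESSE flag for a distal site is positive-in-ES AND negative-in-HSC; strict
mode additionally requires negativity in every supplied differentiated cell
type, covering both readings of the definition.

## Methylation fates

Per-cell-type mean betas feed stage contrasts Δβ = β_late − β_early. Fates:
hypomethylated at Δβ ≤ −0.20, hypermethylated at Δβ ≥ +0.20 (inclusive,
"at least 20%"), stable otherwise; undermethylated means mean β ≤ 0.50
(inclusive). All thresholds operate on the [0, 1] scale; percent output is
display only. The foreground of the cancer-hypermethylation analysis is the
ESSEs undermethylated (≤ 0.50) in *each* normal cell type supplied and
hypermethylated in the cancer contrast — no separate "unmethylated" cutoff
exists, so the undermethylation rule is reused; the background is every
distal site (ESSE or not) hypermethylated in cancer. The
reversion set is the cancer-hypomethylated ESSEs that had gained ≥ 0.20
methylation in the developmental contrast. Cancer contrasts run against
each normal cell type separately; a "highly methylated in normal" cutoff,
where needed, is mean β ≥ 0.50 by symmetry with the undermethylation rule.

## Statistics

* **Rank-sum.** W is the sum of midranks of the first sample. With ≤ 12
  pooled observations and no ties, p is exact: a dynamic program counts
  subsets of ranks per sum, and the two-sided p is min(1, 2·min tail).
  Otherwise a normal approximation with tie-corrected variance and a 0.5
  continuity correction is used; its worst-case deviation from enumeration
  at 6+6 is 0.0155 (without the correction, 0.069).
* **Venn overlap.** "Expected chance intersection" is modelled
  hypergeometrically: a random n_a-subset of an N universe against a fixed
  n_b-subset; expected = n_a·n_b/N, p_enrich = P(X ≥ k),
  p_deplete = P(X ≤ k). This is the canonical distribution for that null;
  the tests verify it against exhaustive subset enumeration for N ≤ 12.
* **Enrichment.** Foreground-vs-background gene sets are tested per set by
  the same hypergeometric tail on the fg∪bg universe (a mode restricts fg
  into bg with bg as universe), with raw p retained and BH q added across
  sets. This deliberately replaces regulatory-domain binomial testing:
  results are not comparable to tools built on that model.
* **KDE.** Gaussian kernels, Silverman bandwidth
  0.9·min(sd, IQR/1.34)·n^(−1/5) unless given; constant input requires an
  explicit bandwidth.

## 4C interaction

Windows of 1,000 bp at 500-bp step tile the region half-open; the percent
denominator is all mapped reads of the profile ("out of all the reads"),
with an in-region denominator behind a flag. Differential interaction is a
two-tailed paired t-test (n−1 df) over per-window percent differences
across a 100-kb region centred on the site of interest; windows pair by
identical coordinates, zero-zero windows are retained (absence of
interaction is information), and an all-zero difference vector returns
p = 1 with a degenerate-variance warning — identical profiles are a
legitimate null, not an error. The bait-proximal zone is included by
default; an exclusion radius is available.

## The synthetic study

The generator plants one site per 12-kb locus on a 2 × 2 Mb genome
(332 sites): each locus carries its own gene — at the site (±2 kb, with a
600-bp CG-rich island block at the TSS) for promoter loci, at 5.0–5.9 kb
for distal loci, so the locus's own gene is strictly nearest and distal
sites always clear the 5-kb rule. The background sequence is CpG-depleted
(95% of CG dinucleotides mutated), as real intergenic DNA is, so the island
scan fires only at the planted blocks.

Planted classes (counts in the default study): promoter 60; constitutive
enhancer 34 and a constitutively marked enhancer that hypermethylates in
cancer 30 (the "retain" arm, and the non-ESSE part of the enrichment
background); ESSEs that in cancer become hypomethylated 70, hypermethylated
46, or stay stable 38 (the "lose" arm); an HSC-gained enhancer 32; inert
distal sites 22. The marked-site mix reproduces a ~61.5/25.6/12.9
lose/retain/gain split. Per-class, per-stage mean betas follow the
qualitative trajectories under study (ESSEs ~0.15 in ES; most rise to
~0.75 in blood; the cancer-hypo group falls back to ~0.30 in cancer; the
cancer-hyper group stays ≤ 0.25 in all normals and rises to 0.75 in
cancer); draws are Beta(mκ, (1−m)κ) with κ = 50, i.e. per-sample sd ≈ 0.05
at mid-range means.

**Mark-signal model.** Tracks are Gaussian noise (sd σ = 1) at 100-bp
resolution plus plateaued signal domains of height 4σ (6 kb wide:
half-width 3 kb with 200-bp Gaussian shoulders) centred on mark-positive
sites. Negative sites receive an equal-sized *decoy* domain offset 5.5 kb
from the probe — distant enough that no tail reaches the ±100-bp window.
Decoys represent the many marked regions a genome carries that are not
probed by the array, and they serve a second purpose: every locus
contributes one domain, so ~50% of each track is covered by signal
regardless of how many probed sites are positive in that cell type, which
places the genome-wide mean midway between background and domain level.
Under the mean-threshold positivity rule this yields a symmetric ~2σ margin
on both sides. A pure narrow Gaussian bump cannot do this: either its area
is too small to lift the track mean above background window-maxima (every
site then calls positive), or a bump broad enough to lift the mean leaks
signal into negative sites' windows. A `peak_offset` parameter shifts
domains off the probe coordinate to exercise the ±100-bp maximum rule.
Three ChIP replicates per cell type mirror, at miniature scale, the
multi-replicate structure of the source datasets (six ES lines, seven HSC,
twelve T/B samples); replicate averaging is what pushes per-site state
error to ~10⁻³.

**4C model.** Background junction reads decay exponentially from the bait
(scale 80 kb); one cell type places 12% of its reads uniformly in a 20-kb
interaction domain 60 kb from the bait. 40,000 mapped reads per cell type,
with raw-read counts back-computed from mapped fractions of 95.9% and
90.8%. Expression values are linearly coupled to promoter methylation
(expr = 10 − 8β + noise), emitted for completeness.

**What the generator does not emulate:** read-level ChIP-seq (fragment
sampling, GC bias, input correction), array probe effects (type I/II
chemistry, cross-hybridization), copy-number or tumor-purity confounding,
realistic gene density or island distributions, and linkage between
neighbouring probes. Passing recovery tests therefore demonstrates the
correctness of the pipeline's logic and thresholds under the stated signal
model — not robustness to the artefacts of real data.

## Problem sizes and determinism

The default study (332 sites, 4 Mb, 9 tracks, 80k 4C reads per cell type)
runs the full pipeline in a few seconds; the focused recovery experiments
use 1,000 sites (mark states, 2 replicates) and 2,000 sites (fate calls,
planted Δβ = −0.3, noise sd 0.05, 2 replicates per stage). These sizes give
every recovery metric a comfortable margin over its pass threshold while
keeping the whole suite fast. One `numpy` generator seeded from the single
configured seed drives every draw in a fixed order, and all writers use
fixed float formatting, so identical seeds give byte-identical files;
rerun determinism is asserted in the integration test.

## Known limitations

Exact rank-sum inference stops at 12 pooled observations (beyond that the
corrected normal approximation is used); nearest-gene assignment is purely
distance-based (no regulatory-domain or contact-based association);
enrichment p-values are not comparable to regulatory-domain binomial tools;
genome-build liftover and IDAT/CEL-level preprocessing are out of scope —
inputs are assumed on one build, as level-3-style tables and tracks.
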