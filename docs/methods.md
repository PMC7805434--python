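# Methods

This note documents the models, parameter choices, numerics and known
limitations of `consreg`. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Consensus model

All coordinates are 0-based half-open (BED convention); any 1-based display
is presentation only. Strand is ignored throughout the interval layer:
histone-mark peaks are unstranded. Book-ended intervals (`a.end ==
b.start`) merge, matching BEDTools `merge` defaults; the test suite
cross-checks `merge`/`intersect`/`subtract` against both explicit per-base
set oracles and the `bedtools` executable.

The evidence-combination gradient is deliberate and encoded as three
distinct operations:

* **Replicates → intersection.** A base must be present in every replicate
  of an experiment. For more than two replicates the intersection of all is
  taken (the conservative reading).
* **Experiments → merge of ≥2-coverage bases.** Seed bases are those
  covered by at least two distinct experiment tracks; the output is the
  merge of maximal seed runs, not the full extents of the contributing
  peaks. A cell line with a single experiment passes through with support 1
  ("at least two *when available*"). The support count attached to a region
  is the maximum number of distinct experiments covering any of its bases.
* **Cell lines → full-extent union.** At tissue and global levels, seed
  bases are covered by ≥2 distinct cell lines, but every input interval
  touching a seed base contributes its *full extent* and the union is
  merged. Whether the union extends to full extents or only the seed
  segments is genuinely ambiguous from the workflow's description; both
  behaviors are implemented (`full_extent` flag on
  `build_higher_consensus`), with full extent as the default.

Classification rules and their interpretations:

* "A window of 1 kb around a TSS" is read as TSS ± 1000 bp (2 kb total),
  consistent with the enhancer rule "distance greater than 1 kb from TSS".
* Promoters retain the **whole** H3K4me3 region overlapping a TSS window,
  not the intersection with the window (region-level selection).
* Enhancer depletion is basepair subtraction of both H3K4me3 regions and
  TSS windows, which guarantees promoter/enhancer base disjointness (a
  tested invariant).
* Active enhancers keep the whole enhancer region when flagged by ≥1 bp of
  H3K27ac overlap (region-level flagging); they are a subset, as whole
  regions, of the enhancer track.
* A cell line emits only the element classes its markers allow (H3K4me3
  alone → promoters only; H3K4me1 without H3K27ac → enhancers but no
  active enhancers).

Broad peaks are filtered at reported *p* < 0.01 (strict inequality; the
−log10 column's ENCODE sentinel −1 means "not reported" and such peaks
raise an error when filtering is requested rather than being silently kept
or dropped). Narrow peaks are not p-filtered. TSS records below score 10
are discarded by default.

## TBA scoring

`P(w_j, n)` comes from count matrices with a pseudocount (default 1.0)
added to every cell before row normalization: zero probabilities would
break the ratio product. The background model defaults to uniform 0.25 per
base; a genome-composition background is available
(`BackgroundModel.from_sequence`). N bases contribute ratio exactly 1 on
both strands, so CREs spanning assembly gaps are scored rather than
discarded.

Numerics: the per-window ratio product is accumulated in log space. Two
choices make strand symmetry `tba(s) == tba(revcomp(s))` exact to the last
bit rather than approximate:

1. each window's log-ratio addends are summed by a *symmetric pairwise
   fold* (column *k* pairs with column *l*−1−*k*, repeatedly), which is
   invariant under reversal of the addend order because float addition is
   commutative;
2. the per-window affinities are summed with `math.fsum`, which is exactly
   rounded and therefore order-independent.

Under reverse complement the window multiset is preserved (window *i* maps
to window *L*−*l*+1−*i* with strands swapped), so both totals are identical
floats. The exhaustive-window product oracle in the tests agrees with the
log-space path to ≤ 1e-9 relative error (measured ~1e-15).

Normalization divides by the window count *L* − *l* + 1 — the quantity raw
TBA is linear in — giving a mean per-window affinity that is
length-comparable.

## Empirical significance

For each PFM, a reference distribution of normalized TBA is built from
random genomic regions: chromosomes sampled proportional to length, starts
uniform, lengths drawn from a caller-supplied sampler (the CLI uses the
CRE length distribution of the input set, recorded in the run manifest).
Regions that are mostly assembly gap (>50% N) are resampled up to 100
times, then an error is raised. Everything is reproducible from a seed.

Thresholds use the upper order statistic with the (k+1)/(n+1) plotting
convention: `threshold(α) = x_(k)` with `k = ceil((n+1)(1−α))` on the
ascending sorted sample, so a fresh null region exceeds the threshold with
probability ≤ α. When `k > n` the cutoff is unreachable at that sample size
and the threshold is +∞ — with the 5,000-region test profile the 1e-04 and
1e-05 bins are unreachable; the production default of 100,000 regions makes
1e-05 reachable. Significance of a score is the smallest cutoff whose
threshold it meets, boundary inclusive; no multiple-testing correction is
applied beyond the stringent 1e-05 default bin. Calibration is verified
empirically: on an i.i.d. background genome the exceedance rate of
`threshold(α)` on 2,000 fresh regions stays within 3·sqrt(α(1−α)/2000) of α
for α ∈ {0.05, 0.01, 0.001}.

PFM quality filtering at annotation time drops matrices built from fewer
than 50 binding sites and matrices enriched in more than 50% of the CRE set
at the active cutoff (recurrently enriched low-information motifs carry no
regional signal). Both limits are configurable.

## Alleles

A CRE allele is the full haplotype sequence of the CRE: each phased diploid
sample contributes two haplotypes, each haplotype's phased SNP alleles are
substituted into the reference sequence, identical sequences are grouped,
and frequencies use the haplotype count 2N as denominator. Only alleles
with frequency *strictly* above the threshold (default 1%) are retained;
exactly 1% is excluded. Multi-allelic SNPs are handled per haplotype;
indels and other variant classes are skipped and counted; unphased
genotypes raise by default (a skip-with-warning mode exists); missing
genotype calls fall back to the reference base. Because alleles differ from
the reference by substitutions only, all alleles share the reference length
and the same PFM-specific reference distribution applies to each. The
supporting fraction of an enrichment is the share of common alleles whose
significance bin is at least as stringent as the chosen cutoff — monotone
non-decreasing as the cutoff loosens (a tested invariant).

## Network capture

An edge (tf, target) of a curated network is captured when some CRE whose
nearest gene is the target enriches a motif of that TF at the cutoff.
Nearest-gene distance is the end-to-end gap (0 when overlapping); ties
break to the smaller (chrom, start) for determinism. Edges whose TF has no
motif in the collection are reported as not-capturable and excluded from
the denominator (only relationships involving TFs in the collection are
evaluated). The null rewires the network by permuting the target column
against the TF column — preserving every TF's out-degree and the target
in-degree multiset — and the p-value uses the add-one estimator
(1 + #{perm ≥ observed}) / (1 + n_perm), never zero, floored at 1/(n+1).

## Synthetic study conditions

The default fixture is desk-scale: 2 chromosomes × 500 kb of i.i.d.
uniform-composition sequence, 3 cell lines in 2 tissues, 2 experiments × 2
replicates per marker track, 600 bp planted elements spaced ≥5 kb apart
(so TSS windows never clip a planted enhancer), 5 sharp 10-mer PFMs, and 50
phased diploid individuals. Peak files carry −log10 p = 5, so broad-format
fixtures pass the p < 0.01 filter. Optional corruption: boundary jitter,
replicate dropout, and decoy peaks placed in exactly one experiment and
kept ≥1.2 kb clear of every planted element, so the only way a decoy can
appear in output is a pipeline defect. Ground-truth BED tracks are written
alongside the peaks directly from the planted design (never by running the
pipeline), and the zero-noise round trip is asserted byte-for-byte.

Two fixture-design points are worth recording because they are easy to get
wrong:

* **Planted-site power.** A finite background genome contains chance motif
  occurrences: a sharp 10-mer expects ~2 exact hits per Mb per strand, and
  those hits enter the reference distribution's extreme tail, pushing
  `threshold(1e-03)` to exactly the planted-site score. The power
  experiment therefore uses a 15-position sharp motif (~26 bits), for which
  chance full or near-full matches in 1 Mb are vanishingly rare; detection
  of a planted consensus site in a 500 bp region at ≤1e-03 is then
  essentially certain for any seed.
* **Allele-specific design.** For a uniformly sharp motif, a
  single-mismatch site still scores far above random background, so a
  "broken" reference allele would be significant too and the supporting
  fraction would be 1, not the share of site-carrying alleles.
  `make_allele_sensitive_pfm` concentrates the information asymmetrically:
  the first position is ultra-sharp (~1000× mismatch cost) and the rest
  moderate (~6×), so the intact site sits far above the genomic null tail
  while the same site broken at position 1 sits far below it, making the
  planted supporting fraction (e.g. 0.5 at 50% haplotype frequency) exact.
* **Permutation-null fixtures.** Target-column rewiring can assign a TF the
  same target twice; in dense networks these duplicate pairs inflate the
  permutation variance relative to the distinct-edge observed statistic
  and make the p-value conservative. Calibration fixtures therefore use a
  sparse network (mean out-degree 2; 300 TFs × 400 targets, 600 edges),
  where the null rejection rate at 0.05 over 200 replicates stays near
  0.05.

What the fixtures do **not** emulate: read-level noise and peak-caller
behavior, realistic peak width/score/significance distributions, sequence
composition structure (repeats, GC skew, CpG islands), linkage
disequilibrium beyond planted haplotype fractions, and real motif
degeneracy patterns. Passing tests therefore demonstrate correctness of the
algebra, scoring, calibration machinery and plumbing on known ground truth
— not biological recall/precision on real ENCODE-scale data.

## Problem sizes and profiles

The reference-distribution default is 100,000 regions per PFM (the
production operating point); tests and the acceptance script use 2,000 to
5,000 regions, 1 Mb genomes, 200-replicate power/calibration experiments
and 1,000-permutation network nulls, chosen so the full suite completes in
well under a minute of compute per experiment while keeping every binomial
tolerance meaningful. Reference distributions are cached by the CLI keyed
on (PFM hash, genome hash, sample size, seed) and reused across reruns.

## Known limitations

* No liftOver/assembly conversion, BigBed/BigWig, or tabix indexing;
  inputs are desk-scale text formats.
* VCFs are scanned sequentially per CRE; for many CREs against a large VCF
  an indexed fetch would be preferable.
* Raw TBA is returned on the natural scale; a pathologically long, sharp
  motif on a perfectly matching long sequence could overflow to +inf
  (log-scale accumulation keeps intermediate products safe).
* The experiment-support count attached to classified cell-line CREs is
  inherited from the defining marker (H3K4me3 for promoters, H3K4me1 for
  enhancers) as the maximum over overlapping consensus segments.
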