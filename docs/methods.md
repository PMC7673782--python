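# Methods

## The editing model

A read from the 249-nt exon IV/V junction amplicon observes the joint
editing state of five adenosines whose genomic 5′→3′ order is A, B, E, C,
D (the conventional naming order is A–E). Each molecule's state is a
binary vector b ∈ {0,1}⁵, so a sample is characterized by a 32-class
isoform distribution. In the default *independent* linkage mode the
frequency of pattern b is ∏ᵢ pᵢ^{bᵢ}(1−pᵢ)^{1−bᵢ} for per-site editing
probabilities pᵢ; an *explicit haplotype* mode accepts an arbitrary
32-vector for linked sites. The per-site marginal of the 32-vector always
equals the configured pᵢ exactly in independent mode — this identity is a
test invariant.

Recoding is data, not code: the reference object carries the codon table
(residue 156 = AUA with sites A and B, 158 = AAU with E and C, 160 = AUU
with D), and the pattern → tripeptide map is derived at run time by
substituting G at edited offsets and translating with the standard genetic
code. Enumerating all 32 patterns yields 24 distinct tripeptides (residue
156 takes 3 values with V doubly encoded, 158 takes 4, 160 takes 2), with
(0,0,0,0,0) → INI and (1,1,1,1,1) → VGV.

## Site calling and tabulation

A site in an aligned read is called EDITED if the base is G with Phred
quality ≥ 20, UNEDITED if A with quality ≥ 20, and MASKED otherwise
(low quality, uncovered, or a non-A/G base — a sequencing error to C or T
carries no editing information, so it is excluded rather than counted as
unedited). Per-site percentages use every read covering the site; the
32-class isoform table uses only *complete* reads in which all five sites
were called, since a partial read cannot be assigned to a class without
imputation. The two tables therefore draw on slightly different read
sets; on complete reads the site marginal of the isoform table is an
exact identity, which the tests assert. A site covered by no read is
reported as missing, never as 0%.

## Alignment

Amplicon reads need no genome-scale aligner: every gapless placement of
the read and of its reverse complement along the 249-nt reference is
scored by mismatch count, the five site columns being excluded so that
heavily edited reads are not penalized. Reads are accepted when the best
placement has at most `max_mismatch_frac` (default 0.1) × read length
mismatches; rejections carry a reason code (`empty`, `too_long`,
`too_many_mismatches`). Reverse-strand reads are re-oriented before
calling. Externally produced SAM/BAM restricted to the amplicon locus can
be ingested instead; both routes produce identical downstream site calls
(a round-trip test invariant). Overlapping mates are merged by taking the
higher-quality base per position; confident disagreements (both mates
≥ Q20) are masked. Indels are not modeled — deletions become masked
positions, insertions are dropped — which is adequate for substitution-
dominated amplicon data and is the reason the aligner is gapless.

## Replicate statistics

The unit of replication is the animal: each mouse contributes one
frequency per site and one proportion per isoform. Read-level tests would
be wildly anticonfident at 10⁴–10⁶ reads per mouse. Two-group comparisons
use Student's t-test when both groups pass Shapiro–Wilk at α = 0.05, and
Mann–Whitney otherwise — always when a group has fewer than three values
or is constant (two identical constant groups give p = 1 by convention,
as the data carry no evidence). Mann–Whitney uses the exact null
distribution for small untied samples and the tie-corrected normal
approximation otherwise (scipy's automatic policy). Isoform effects are
reported as the KO/WT ratio of group *mean* proportions, matching the
convention of ratio-of-displayed-group-summaries; rows whose WT mean
abundance is below 5% are flagged low-abundance rather than dropped.
Multiple-testing correction defaults to `none` (mirroring raw p < 0.05
reporting across such tables) with Benjamini–Hochberg per region
available via `--adjust bh`.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure of the real assay:
multinomial sampling of isoform patterns per read, uniform substitution
errors (default rate 10⁻³), Gaussian Phred scores (mean 35, sd 3) with a
1% low-quality dropout below the Q20 gate, cohorts of 6–12 mice per
genotype at 10⁴–10⁵ reads per mouse, and a between-mouse biological sd of
1 percentage point on the true per-site probabilities, consistent with
the low inter-animal variability of deep amplicon data. It does **not**
emulate PCR amplification bias, strand-specific error profiles, indels,
primer artifacts or position-dependent quality decay; passing tests
demonstrate correctness of the computation under the stated sampling
model, not robustness to those real-data artifacts. Default per-site
probabilities follow the established regional pattern (A, B and D sites
more edited than C and E).

For replicate-level statistical experiments (power and type-I error over
hundreds of repetitions) samples are drawn at the multinomial layer
(`sample_pattern_counts`) rather than rendered into bases and re-aligned;
the downstream replicate statistics see the identical distribution, and a
separate bit-exactness test guarantees the rendered path reproduces the
sampled tallies exactly at zero error rate. Problem sizes used by the
statistical suites: 200 repetitions for power (n = 10/10 mice, 50k
reads/mouse, +2 pp shift), 1000 repetitions for null calibration
(20k reads/mouse), chosen to give Monte-Carlo standard errors well inside
the asserted bands.

## RiboMeth-seq scoring

Alkaline degradation cleaves at random phosphodiester bonds; a
2′-O-methyl at nucleotide m protects the bond 3′ of m, depleting read
5′-ends at position m+1 (the cleavage-offset convention is a single
shared constant between generator and scorer). The score at an end-count
position p is `max(0, 1 − n_p/w)` with w the weighted mean of neighbor
counts at offsets ±1…±k, weights k, k−1, …, 1 (default k = 6), excluding
the cleavage positions of other annotated sites from the neighborhood.
This is the "deficit against a weighted local average" family of
RiboMeth-seq scores; which published variant a given laboratory used is
often unstated, so the window and weights are configurable. The score is
scale-invariant, monotone decreasing in n_p, 1.0 at full protection and 0
on a flat profile; it is undefined (reported missing) when the local mean
is zero. Real-tissue methylation levels are not reproduction targets
here; the module is validated on synthetic Poisson profiles where the
recovered scores must rank-match the configured protection factors.

## Calorimetry

The four closed-form derivations (RER, energy expenditure, glucose and
lipid oxidation) are applied elementwise to V̇O₂/V̇CO₂ tables assumed
already normalized to kg⁰·⁷⁵; units are labels only and no conversion is
attempted, so outputs are correct up to the unit of the supplied inputs.
Negative oxidation values are preserved and flagged, never clipped, and
RER outside [0.6, 1.3] is flagged as physiologically implausible.

## Numerical and design choices

- All offsets are 0-based half-open; region strings (`chrom:start-end`)
  are 1-based inclusive at the boundary and converted on input.
- Pattern bins are indexed with site A as the most significant bit in
  genomic order (A,B,E,C,D); labels list edited sites in naming order.
- Frequencies are kept at full float precision internally and printed
  with two decimals in TSVs.
- All randomness flows from one root seed: cohort expansion uses numpy's
  `SeedSequence` to derive independent per-sample seeds, making every
  artifact byte-reproducible for a fixed config.
- The filler sequence around the recoded codons is a fixed arbitrary
  string; no computation depends on its identity.

## Known limitations

- The gapless aligner cannot place reads spanning structural variants or
  large indels; such reads are rejected by the mismatch cap.
- Paired-end support is overlap-merging of already-aligned mates; there
  is no insert-size model in the generator (single-end full-span reads
  are the default layout).
- The 5% low-abundance flag and the α = 0.05 tiers are conventions, not
  inferences; the type-I calibration guarantee applies to the site-level
  test under the stated generator, not to arbitrary real-data designs.
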