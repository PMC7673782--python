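# ampedit

Quantification of combinatorial A-to-I RNA editing from amplicon deep
sequencing, with companion RiboMeth-seq 2′-O-methylation scoring and
indirect-calorimetry derivations.

The serotonin receptor 2C transcript (*Htr2c*) carries five editable
adenosines — the A, B, C, D and E sites — clustered in exon V (genomic
5′→3′ order A, B, E, C, D). Inosine is read as guanosine, so editing
appears as A→G mismatches between cDNA reads and the genome. The joint
state of the five sites defines 2⁵ = 32 mRNA isoform classes; because the
sites sit inside three codons of the receptor's second intracellular loop
(residues 156, 158, 160), those 32 classes translate into 24 distinct
protein variants, from unedited **INI** to fully edited **VGV**.

`ampedit` is for researchers quantifying this kind of editing from deep
amplicon sequencing of the spliced exon IV/V junction (a 249-nt product,
10⁴–10⁶ reads per sample, 6–12 animals per genotype). It provides:

- a **synthetic-data generator** (reference, Phred-scored FASTQ reads with a
  configurable 32-class isoform distribution, RiboMeth-seq end-count
  profiles) so every stage is testable without downloads;
- an **anchored gapless aligner** for amplicon reads (SAM/BAM ingestion is
  also supported for externally aligned data);
- **per-read site calling** with the standard Q≥20 quality gate: a site is
  EDITED (G), UNEDITED (A) or MASKED (low quality, non-A/G base, or
  uncovered);
- per-sample **site frequencies** and the **32-class isoform table** with
  protein recoding;
- **replicate-aware differential testing** (the mouse is the unit of
  replication): Student's t-test when both groups pass Shapiro–Wilk,
  Mann–Whitney otherwise, with optional Benjamini–Hochberg correction;
- **RiboMeth-seq scoring**: the 2′-O-methylation protection score
  `max(0, 1 − n_p/w)` where `w` is a linearly weighted local mean of
  5′-end counts (window k = 6);
- **indirect calorimetry**: RER = V̇CO₂/V̇O₂, energy expenditure
  `1.44·V̇O₂·(3.815 + 1.232·RER)` (kcal/day/kg⁰·⁷⁵), glucose oxidation
  `(4.545·V̇CO₂ − 3.205·V̇O₂)/1000` and lipid oxidation
  `1.672·(V̇O₂ − V̇CO₂)/1000` (g/min/kg⁰·⁷⁵).

## Worked example

`examples/01_simulate_and_profile.py` simulates one 20,000-read sample at
hypothalamus-like editing levels, aligns it and profiles it:

```
aligned 20000 reads (0 rejected), 18950 with all five sites called

per-site editing (truth vs estimate, %):
  A:  65.0  vs 64.54
  B:  50.0  vs 50.03
  E:  10.0  vs  9.63
  C:  15.0  vs 15.45
  D:  35.0  vs 34.88

top mRNA isoform classes (% of complete reads -> protein):
  AB     16.28%  VNI
  A      15.82%  VNI
  none    8.92%  INI
  AD      8.78%  VNV
  B       8.70%  MNI
```

The per-site estimates recover the generating probabilities to within
binomial sampling error; each isoform row is one combination of edited
sites with its share of fully-called reads and the protein it encodes.
`examples/02_differential_cohort.py` adds a 10-vs-10-mouse comparison with
a +3 percentage-point KO shift at the C site and prints the per-site
differential table (the C row significant at p < 0.05, the rest null);
`examples/03_ribomethseq.py` and `examples/04_calorimetry.py` cover the
other two capabilities.

A complete simulate → align → profile → differential run is available from
the shell:

```sh
ampedit demo --outdir demo_run --seed 1
```

which writes the reference FASTA, per-sample FASTQ/SAM and TSV profiles,
both differential tables, and a manifest with per-stage read counts.

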