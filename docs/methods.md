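# Methods

This package reimplements, as tested library code, the bespoke computational
procedures of a neem (*Azadirachta indica*) multi-omics analysis: genome-wide
microsatellite (SSR) mining and cross-genotype polymorphism calling, filtered
pileup SNP/InDel calling with coding-effect annotation, RPKM expression
profiling screened against metabolite concentrations, and internal-standard
calibration-curve quantification of seed limonoids. Because the original
sequencing data are not required, every stage runs against a bundled
synthetic panel generator that emits machine-readable truth tables; the
sections below describe each model, its parameters and the design choices
that were genuinely open.

## Synthetic genotype panel

`neemomics.simulate.generate_panel` builds a reference assembly of
`n_contigs` x `contig_length` (default 5 x 120 kb) in which planted SSR runs
and protein-coding gene bodies alternate with non-repetitive spacers. Spacers
are rejection-sampled so that they contain no SSR at detection thresholds,
and the bases adjacent to each planted run are constrained so the run cannot
extend; the generator asserts that scanning the finished contig recovers
exactly the planted loci, so detector precision and recall are measurable
against a clean truth set. Gene bodies are valid ORFs (ATG ... stop, no
internal stop codon, no SSR) with zero or one intron, on either strand, with
GFF3-style CDS phases; with the defaults (400 genes of 240-600 coding bases)
genes cover roughly 30% of the genome. Planted SSRs never overlap genes —
the genic/non-genic split of the summary stage is therefore exercised with
constructed gene spans in the tests, not on the panel.

Query genotypes (default two, mirroring a three-genotype design) differ from
the reference only at truth-table records:

- **SSR repeat-number changes** at `n_ssr_polymorphic` loci per genotype
  (default 60 of 550), drawn as +/-1..4 repeat units, with a 5% chance of
  whole-locus deletion; a shared core (one third) is planted polymorphic in
  every genotype so the concordance stage has a non-trivial intersection.
  Changes that would leave fewer than two copies flip sign instead.
- **SNPs** at rate 0.0029/base and **InDels** (1-10 bp, uniform) at
  0.00022/base — the per-kilobase densities the marker analysis reports
  (2.9 and 0.22 per kb). SNPs avoid SSR runs; InDels additionally avoid a
  110 bp margin around every SSR so that flank anchoring and repeat-count
  arithmetic stay well-posed, and keep a 15 bp separation from each other
  so left-alignment cannot merge adjacent events.

InDel truth records are stored VCF-style (anchor base plus inserted/deleted
sequence) and left-aligned with the same normalization the caller applies,
which makes truth-vs-call comparison exact even inside short repeats. SSR
repeat changes are additionally exported as left-aligned indel records
(`ssr_indel_truth`), because sequencing reads faithfully carry them and the
variant caller will, correctly, call them.

All randomness flows from a single seed through fixed `SeedSequence`
streams; identical configs give byte-identical panels.

## Read simulation

The panel retains an exact reference/query alignment map (match blocks
separated by the planted insertions and deletions), so
`simulate_reads` can emit every read at its true reference origin with the
correct CIGAR — including soft-clips when a read begins or ends inside an
inserted segment — without invoking an aligner. Reads are error-free,
fixed-length (100 bp), single-end, Q40, mapping quality 60; start positions
are uniform with overhanging starts clipped to the contig, which keeps mean
depth equal to the nominal coverage (default 30x) including contig ends.
Not modelled: sequencing errors, quality calibration, GC bias, paired ends,
strand bookkeeping. Consequently, caller recovery figures on this panel
measure the pileup/filter/normalization logic, not robustness to noisy
bases; the quality filter is still exercised because the Phred-binomial
score depends on depth.

## SSR detection

`scan_ssrs` reports every maximal perfect tandem run of a primitive 1-6 bp
motif meeting per-unit-length minimum copy numbers. Defaults are the cited
mining tool's shipped configuration (mono >=10, di >=6, tri-hexa >=5;
compound merging within 100 bp), since the study names the tool but prints
no settings. The scanner works on a vectorized shifted-equality encoding:
positions where `s[i] == s[i-k]` form runs whose maximal stretches are the
period-k regions; spans are trimmed to whole copies, runs containing N are
split, and a region divisible by a shorter primitive unit is reported only
under that unit. Equivalence with an exhaustive per-position enumeration is
asserted on 1,000 random 10 kb sequences. Canonical classes ("AAG/CTT")
take the lexicographically smallest string over all rotations of the motif
and of its reverse complement. Compound merging is reported separately
(`find_compound`); compound loci are excluded from polymorphism calling
because repeat-count comparison across compound structures is ill-defined.

## SSR polymorphism

Each reference locus travels with 100 bp of immediately adjacent sequence on
both sides. Flanks are located in the query by exact 31-mer seeds at three
spread offsets — two mismatches cannot hide all three — then verified
full-length with at most 2 mismatches per flank. A locus is matched only if
both flanks place uniquely, on one contig, in consistent orientation and
order, with an inter-flank span no larger than the locus length + 200 bp.
Ambiguous placements are dropped rather than best-scored: a marker locus
must be locus-specific to be usable. The inter-flank sequence is re-scanned
with a relaxed two-copy minimum; class-conserved count differences are
`polymorphic`, absence of the class is `polymorphic` with query class
"absent", a different class is `class_changed`, and N makes the locus
`unresolved`. The concordance shortlist intersects the per-genotype
polymorphic sets on reference locus identity.

Under the default SNP rate, a flank occasionally carries three or more SNPs
(about 0.7% of loci) and is then — by contract — unanchorable; measured
sensitivity is ~0.97-0.99 with precision 1.0, and the concordance shortlist
can fall short of the truth intersection by the same one or two loci.

## Variant calling and annotation

`pileup_call` builds per-site base and gap columns from the CIGAR of every
read (mapping quality >= 20), then emits a haploid-style call wherever one
alternate allele reaches 80% of its column — assemblies of a predominantly
selfing tree are compared as genotypes, not as heterozygous sites. Variant
confidence is `-10 log10 P(X >= alt | depth, 0.01)` under a binomial error
model with a fixed 1% per-base error rate; the published filter ("quality
> 30, minimum depth 10 reads") is applied as variant quality plus the
depth floor, with failing calls retained and labelled `low_depth` /
`low_qual`. Insertions and deletions are taken from gap operations anchored
at the preceding base and left-aligned before reporting.

Effect annotation classifies position against gene models with precedence
exonic > intronic > upstream/downstream (within 5,000 bp of the nearest
gene, strand-aware; the window is the conventional annotation-tool default,
not stated in the study) > intergenic. For CDS SNPs the affected codon is
rebuilt on the coding strand and translated: synonymous, nonsynonymous,
start_lost (reference codon ATG at codon 0), stop_gained, stop_lost. The
tests check every planted exonic SNP against an oracle that translates the
full reference and mutant proteins and diffs them.

`marker_density` is `count / genome_size * 1000`, averaged over genotypes
and reported to two significant figures (full precision retained).

## Expression and the metabolite screen

RPKM is `count * 1e9 / (gene_length * total_mapped)` with the per-tissue
total taken as reads mapped to the gene set, making the matrix
self-contained. On a 400-gene panel this denominator is small, so absolute
RPKM values are inflated relative to a whole-transcriptome experiment; the
screen is scale-free (Pearson correlation and within-gene contrasts), so
only profile shapes matter.

The simulator plants `n_corr_genes` (default 50) whose expected RPKM is
exactly proportional to the metabolite vector across tissues — column
totals are solved so the proportionality survives the RPKM denominator —
and mean-one lognormal multiplicative noise (CV default 0.1) is applied on
top. The planted metabolite vector is a factor-two geometric gradient over
the seven tissues (developing endosperm 2000 down to mature leaf 31.25
pg/ug), following the measured azadirachtin tissue ordering. This gradient,
rather than a single-tissue spike, is what makes the r >= 0.9 screen
selective: with only seven tissues, a spike-shaped target would be matched
at r >= 0.9 by 1-2% of unrelated genes purely from small-sample correlation
geometry, and the screen's false-discovery rate could not stay below 10%
over hundreds of background genes. Background genes mix broadly expressed
profiles (lognormal baseline, per-tissue lognormal variation sigma = 0.3),
8% single-tissue-specific genes and 4% silent genes. A single-tissue
endosperm-specific gene correlates with the gradient at r ~= 0.88 — below
the strict tier by construction of the gradient, not by exclusion.

The screen computes per-gene Pearson r over tissues (genes with zero
variance are flagged undefined, never silently zero), tiers candidates at
r >= 0.8 and r >= 0.9 (both inclusive; the study mixes "above +0.8" with
">= 0.9", so both thresholds are parameters) and requires the
high-metabolite tissue to out-express the low-metabolite tissue
(endosperm vs leaf by default). The network-clustering step of the original
workflow is represented by hierarchical clustering of tissues plus this
per-gene correlation screen — the two outputs the analysis actually used —
not by a full weighted-network implementation, for which no parameters are
reported. Label permutation (`permutation_null`) re-runs the tier count
under shuffled tissue labels; the test requires the median permuted tier to
be at most one fifth of the observed tier, a robust summary because the
minority of permutations that fix the top tissue retain part of the signal.

`ddct_fold_change` implements relative qPCR quantification,
`2^-(dCt_sample - dCt_calibrator)` against a reference gene, with
replicates averaged on the Ct scale before differencing.

## Metabolite quantification

Calibration standards form a geometric dilution series (the published
azadirachtin series doubles from 15.6 pg to ~1 ng on column, a 64-fold
span; nimbin's printed endpoints 3.4 pg-0.25 ng are not an exact
power-of-two chain, so endpoints and level count are parameters).
`fit_calibration` is an unweighted least-squares line of the
analyte/internal-standard response ratio on amount — no weighting is
specified in the study; 1/x weighting is available as an option — and r is
the product-moment correlation of ratio vs amount. `quantify` inverts the
line and scales through the preparation chain (2 mg dry tissue, 1 mL
extract, 5 uL aliquot into a 50 uL final volume, 10 uL injected):
`pg/ug = amount * (final/injection) * (extract/aliquot) / tissue mass`.
Ratios at or below the intercept are flagged below-quantification rather
than reported negative; amounts outside the calibrated range are flagged
extrapolated. `fold_range` truncates the high/low quotient to an integer —
the only rule that reproduces both printed spans (64 from 64.1, 73 from
73.5). Noise-free round trips recover planted concentrations to floating
precision, and at 1% multiplicative noise the fitted r stays at or above
0.998 in >= 95% of replicates, consistent with the published 0.998-0.999
coefficients.

## Problem sizes and numerical choices

Defaults were chosen once as a realistic, fully checkable study miniature:
600 kb of genome across 5 contigs, 550 SSR loci, 60 polymorphic loci per
genotype, ~1,700 SNPs and ~100 InDels per genotype at 30x coverage, 400
genes over 7 tissues, 1,000-replicate calibration Monte Carlo. Ties in the
candidate ranking break by gene id; indel normalization follows the
standard trim-and-extend left-alignment; degenerate inputs (constant
metabolite vector, zero-variance genes, empty call sets, truncated flanks)
are flagged or excluded with named reasons rather than silently dropped.

## Known limitations

- Reads are error-free and single-end; caller robustness to base errors is
  not measured here.
- The SSR polymorphism stage is assembly-to-assembly, as in the original
  workflow; genotyping from raw reads is out of scope.
- Gene models have no UTRs and at most one intron, and splice sites are not
  sequence-realistic; effect annotation is exercised on CDS structure, not
  on splice-site disruption.
- The panel's SSRs are all intergenic; genic-SSR summaries are validated on
  constructed inputs.
- Absolute RPKM magnitudes on the small panel are inflated by the
  gene-set-restricted denominator (see above).
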