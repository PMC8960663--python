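# Methods

This note documents the models and conventions behind each analysis stage,
the synthetic-data generator that stands in for real sequencing data, the
numerical choices, and what the recovery tests do and do not demonstrate.

## Coordinates, orientation and formats

All intervals are 0-based half-open (BED convention) on both strands.
Strand never changes how an interval is stored, only how sequence and
signal are *read*: `fetch_oriented` returns the reverse complement on the
minus strand, so every downstream vector runs 5'→3' in transcription
orientation, with "upstream" meaning 5' of the exon. Genome sequence is
restricted to {A,C,G,T,N}; other IUPAC ambiguity codes are mapped to N on
read (real genomes contain gaps and ambiguous calls, and a single missing
symbol keeps every downstream rule simple). Signal is consumed as text
bedGraph with sorted, non-overlapping intervals; uncovered positions are
*missing*, and each consumer decides what missing means (excluded from GC
means; converted to 0 in signal metaprofiles, where that rule is part of
the procedure being reproduced).

## Event filtering

One differential-inclusion record carries an exon interval, a comparison
group, a replicate index, control and treatment PSI, and a Bayes factor.
The per-group chain:

1. **Evidence.** Bayes factor strictly greater than the threshold
   (default 10.0). The strict inequality is deliberate; 10.0 itself fails.
2. **Replicate reconciliation.** All records for an exon key (chrom,
   start, end, strand) are considered together, whatever their evidence:
   any two records with opposite ΔΨ sign discard the exon; ΔΨ = 0 is
   direction-ambiguous and discards it. Otherwise the exon is retained
   when at least one record passes the threshold (`require_all_reps`
   tightens this to all records); the consensus ΔΨ is the mean, and the
   direction is *included* (ΔΨ > 0) or *skipped*. The discard rule is
   inherent to the procedure; the acceptance rule (≥ 1 passing replicate)
   is this package's documented choice and is configurable.
3. **Redundant forms.** Exons sharing chrom + strand and an identical 5'
   or 3' boundary (boundary identity taken in transcription orientation:
   the 5' boundary is `start` on +, `end` on −) are alternate forms of one
   event; any form shorter than 50 % of the longest in its boundary group
   is discarded. Forms at exactly 50 % are kept.
4. **Deduplication.** Exact coordinate duplicates collapse to one call;
   duplicates with conflicting directions are discarded (the natural
   extension of the opposite-effects rule to within-group duplicates).
5. **Cross-group discard.** An exon called with opposite directions in two
   different groups is removed from every group.

Every discard is logged with its reason. A noteworthy non-property: the
composed chain is **not** monotone in the Bayes threshold. Raising the
threshold can remove a long exon form whose presence had been suppressing
a short redundant form (or one side of a cross-group conflict), so the
short form resurfaces. Monotonicity holds at the reconciliation stage
only; the binding correctness check is exact agreement with an independent
brute-force implementation that materializes every rule literally.

**Event classes** against transcript models (ordered exon chains per
gene): *cassette* — internal in one transcript and absent from another
transcript of the gene in which both flanking exons appear with identical
boundaries; *retained intron* — the exon equals two adjacent exons of
another transcript plus the intervening intron; *bleeding exon* — shares
exactly one boundary with an annotated exon and runs past the other
boundary into the intron; *other* — everything else. Classes are assigned
with that priority, so each exon gets exactly one.

The **expressed-exon background** is the set of exons with a nonzero count
in every named control sample; it anchors the GC background scalar and the
trinucleotide background spectrum.

## GC metaprofiles

Per exon: 500 upstream flank positions at native scale, 100 body bins, 500
downstream positions, all oriented. Body binning covers window
[i·L/100, (i+1)·L/100) with fractional base weights — exact for any exon
length, and equivalent to integrating the per-base step function (the
implementation interpolates the cumulative sum; an independent per-base
loop oracle confirms agreement to 1e−12 on lengths 37/100/101/250). N
bases and positions clipped at chromosome ends are missing and excluded
from numerator and denominator of every mean, never zero-filled (the
zero-fill rule belongs to the signal procedure, which states it; GC does
not). Aggregation is the per-position mean over exons of available values,
with per-position n recorded.

Smoothing is a *trailing* moving average (window 10 positions by default),
`smoothed[t] = mean(raw[t−9 … t])`, with shorter windows at the left edge
— the semantics of a spreadsheet-style moving average. Smoothing is
applied to the aggregated profile (not per exon); the order is
configurable. Note the first `window − 1` positions of each region after a
level change mix the two levels; recovery statistics therefore exclude
each region's warm-up positions.

The background is a single scalar: the mean over expressed exons of each
exon's whole-body GC fraction, unweighted by exon length, drawn as a flat
reference line.

## Splice-site trinucleotides

Nomenclature is intron-centric: the **3' splice site** (acceptor) sits at
the exon *start*, the **5' splice site** (donor) at the exon *end*, both
in transcription orientation. Two window conventions are implemented:
`exonic` (default) reads the three exonic bases adjacent to each junction;
`intronic` reads the three intronic bases across it. The exonic default
reflects that the reported site trinucleotides in this line of analysis
(e.g. acceptor-side TCC/CCC) are not the canonical GT/AG intronic
dinucleotide context; both conventions are exposed and switchable.

Spectra are exact 64-category counts; exons whose window contains N or
leaves the chromosome are excluded and counted, so counts + exclusions
equal the input size and frequencies sum to 1 exactly. Enrichment is the
elementwise frequency ratio against a background spectrum; entries with
zero background frequency are flagged undefined rather than divided.

## Signal metaprofiles

The scale-regions geometry: 25 upstream bins (500 bp / 20 bp), 5 body bins
(body rescaled to 100 bp), 25 downstream bins. Missing positions —
uncovered track, coverage gaps, flanks beyond chromosome bounds — are
converted to 0 *before* any averaging; the rule is unconditional. Body
rescaling projects the L per-base values onto 100 positions by
fractional-weight mapping, which conserves signal mass for any L (not a
fixed-step interpolation). Minus-strand vectors are reversed so bins read
5'→3'. The profile is the per-bin mean across exons with standard error
= sample SD (n−1) / √n; a single exon yields a mean with no standard
error. Correctness is anchored by a per-base materialize-zero-fill-average
oracle over random track/exon pairs at awkward lengths (40/100/137/600).

## Expression PCA

Size factors follow the median-of-ratios estimator: for genes with
strictly positive counts in all samples, the per-sample median of
log(count / gene geometric mean), exponentiated — exactly the DESeq2
estimator (the median is taken in log space, which matters for even gene
counts). Because size factors only fix *relative* library sizes, the
returned factors are rescaled to geometric mean 1: the unique gauge in
which re-estimating factors on normalized counts returns exactly 1 and
renormalization is idempotent. (Raw factors are not a fixed point:
re-estimation returns their geometric mean in every sample.) The exact
two-sample doubling case gives (1/√2, √2) in either gauge. A test
cross-checks against pydeseq2 in the common gauge.

Normalization divides each sample by its factor. Genes with mean
normalized count below 2 are removed ("fewer than two normalized reads"
read as the mean across samples; the max-across-samples alternative is a
flag). Per gene, mean and squared coefficient of variation CV² =
variance/mean² use the unbiased (n−1) variance — with biased variance a
two-replicate design collapses. Highly variable genes are selected by OLS
of log CV² on log mean (plain least squares; "linear fit" without
qualification) and taking the largest positive residuals (default 100);
ties break by larger CV², then gene id. PCA runs on X[s,g] =
log(normalized + 1) over the selected genes with samples as observations,
gene-centered but not variance-scaled (HVG selection already handles
variance heterogeneity); variance fractions are eigenvalue shares over all
computed components and sum to 1.

## Synthetic data generator

The generator emulates the data structures of a two-replicate,
multi-group exon-inclusion study with an associated nucleosome-occupancy
track, with every planted parameter recorded in a truth table. One global
seed drives four named sub-streams (genome, events, counts, signal) so
each artifact regenerates identically in isolation; all outputs are
byte-deterministic.

**Genome.** Cassette-exon genes (3–5 exons of 80–250 bp, introns
600–1200 bp, ≥ 1 kb intergenic background, strands ~50/50) tiled on one
synthetic chromosome, each with two transcripts: with and without the
middle alternative exon. The alternative exon's class (included / skipped
/ null / discordant decoy) is drawn from configured fractions (defaults
0.3/0.3/0.35/0.05). Bases are independent draws with P(G or C) equal to
the class GC target — included 0.65, skipped and background 0.45 by
default, matching the contrast the analysis is meant to detect. Per-base
independence (no dinucleotide model) suffices because the statistic is a
per-position average. Redundant decoys (10 % of affected exons) overlap a
parent affected exon, share one transcription-orientation boundary, and
are strictly shorter than half the parent.

**Events.** Affected exons get |ΔΨ| ~ |Normal(0.3, 0.1)| (truncated to
keep PSI in [0,1]), positive for included and negative for skipped, in
every replicate, with Bayes factors log-uniform on (15, 1000); null exons
get small same-sign shifts with Bayes factors on (0, 5); discordant decoys
alternate ΔΨ sign between the two replicates at high Bayes factors. Each
exon appears in a random nonempty subset of the comparison groups — except
redundant decoys, which inherit their parent's groups, since a redundant
form is an alternate record of the same comparison (without this the decoy
could appear in a group where its longer parent is absent and legitimately
survive the length rule). PSI values are emitted directly rather than
simulated from reads: the filters operate on caller output, and the caller
itself is out of scope.

**Motif planting** is *derandomized*: with an acceptor (or donor) motif
configured at rate r, exactly round(r·n) of the affected exons get the
motif written at the site, the remaining affected and all background exons
have motif-matching sites resampled away, and background exons receive the
motif at exactly its expected natural rate for the background GC. The
planted enrichment (target rate / natural rate) is then recovered without
binomial noise stacked on top of it — at the study sizes (500 affected,
~1500 background exons, natural TCC rate ≈ 0.014) fully random planting
would bury a 3-fold enrichment under ±0.5 of ratio noise, which is a
property of small-n ratio estimation, not of the analysis under test.

**Counts.** Gene means are lognormal around 100 (log-SD 1); counts are
negative binomial with Var = μ + αμ², α = 0.05 (α ≤ 1e−12 falls back to
Poisson), scaled by per-sample size factors uniform on (0.5, 2). A planted
subset of 100 of 5000 genes is highly variable: dispersion ×20 and a
between-group shift of 2^±2 per group (random direction per gene) across
two groups of three samples. These values come from an a-priori power
analysis: with 6 samples the log CV² estimate has SD ≈ √(2/5) ≈ 0.63, so
the HVG-vs-null separation must exceed the ~1.8 null tail at 4900 genes by
several multiples of 0.63 for ≥ 90/100 recovery, and the between-group
shift must dominate the within-group log-variance for the group axis to
carry > 0.5 of the PCA variance at every seed (measured min 0.64, mean
0.69 over 60 seeds — the mean matching the ~2/3 PC1 share typical of
strong perturbation designs). Exon-level counts guarantee a nonzero count
in every control sample for exons designated expressed.

**Signal.** Baseline 1.0 over the chromosome, a Gaussian bump of amplitude
4 and width (SD) 50 bp centered on each included exon, and coverage gaps as
randomly chosen 100 bp blocks totalling 10 % of the genome (missing, not
zero). The track is built at 1 bp resolution and run-length merged.

**What the generator does not emulate:** read-level sampling and mapping
noise, splice-graph complexity beyond one cassette exon per gene,
dinucleotide/CpG structure, isochores, correlated nucleosome arrays,
assembly-scale genomes. Passing recovery tests therefore demonstrate the
correctness of the computations and filters, not robustness to alignment
or quantification artifacts in real data.

## Recovery statistics and problem sizes

The acceptance scenarios run at deliberate desk scale: 20 random tables of
≤ 300 records for filter-oracle equivalence; 300 exons for GC recovery
(region means compared at ±0.02, excluding each region's smoothing warm-up
— at n = 300 the per-position SD alone is ≈ 0.029, so only region means
carry the stated precision); 500 affected exons for the 3-fold motif
enrichment (±0.3); ~300 exons per direction for the nucleosome profile,
where the included-set peak must land in the central body bins and exceed
the flank mean by > 3 SE, and the skipped set is tested for flatness with
the single body-vs-flank contrast (a per-bin maximum at a 3 SE threshold
would false-alarm on ~1 in 7 null datasets by multiplicity alone); 20
seeds of 5000 genes for HVG/PCA recovery. Total runtime is a few seconds.

## Known limitations

GFF3 annotation input is not implemented (BED6 with structured names is
the annotation dialect); bigWig is not read or written; bleeding-exon
subtypes (alternative 5' vs 3') are not distinguished; the converter from
raw MISO output files to the comparison-table TSV is left to the user.
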