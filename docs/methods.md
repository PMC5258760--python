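# Methods

This note documents the models, conventions and numerical choices behind
`mirqtl`, and what the synthetic-data tests do and do not demonstrate about
real data.

## Differential expression from pooled libraries

The sequencing design this pipeline targets pools biological replicates
into a single library per (genotype, treatment, time point) cell — twelve
libraries for two genotypes × control/heat × 1/6/24 h.  With no replicates
there is no within-condition variance estimate, so significance comes from
Fisher's exact test on raw counts: for each miRNA and heat-vs-control
contrast the 2×2 table is (miRNA reads, library total − miRNA reads) in
each condition.  Two-sided p-values use the point-probability rule (sum of
all tables, margins fixed, with probability ≤ the observed, ties included).
Raw counts feed the test; TPM (count / library total × 10⁶) feeds only the
fold change.  Library totals default to the column sum of the supplied
(confirmed) matrix; a `total_reads` metadata column overrides this when the
caller wants normalisation against total sequenced reads
(`--total-from meta`).

Choices the data format forces but the method leaves open:

* **Pseudo-count** — 0.25 TPM added to both sides of the fold-change ratio.
  It keeps ratios finite with a zero side, and is small against the 10-read
  confirmation floor (10 reads ≈ 10 TPM at 10⁶ depth), so it never moves a
  confirmed miRNA across the two-fold gate on its own.
* **FDR family** — Benjamini–Hochberg within one contrast, over all
  confirmed miRNAs, matching per-comparison DE lists.
* **Confirmation** — a miRNA enters testing only with ≥ 10 reads in at
  least one library (inclusive threshold).

**What the exact test can and cannot control.**  Fisher's test models
within-condition sampling as hypergeometric, i.e. Poisson-level noise.
Under that model the three gates (|log₂FC| ≥ 1, p ≤ 0.05, FDR ≤ 0.05) are
strongly conservative at 10⁶-read depth, and the null-calibration test runs
the generator in its Poisson limit (dispersion → 0) to verify a
false-positive fraction well under 5%.  Biological overdispersion between
pooled libraries (the generator's default φ = 0.1, variance μ + φμ²) is a
*between-library* effect that no replicate-free test can absorb: under it,
observed log₂ ratios have sd ≈ 0.65 and a sizeable share of null miRNAs
passes all gates.  This is a property of the pooled design itself, not of
the implementation, and is why the synthetic fixture (like real pooled
sRNA studies) produces DE lists that should be read as heat-responsive
*candidates* feeding the downstream QTL filter, not as a
false-discovery-controlled set.

miRNAs DE in at least one contrast are classified across the two genotypes:
same majority sign in both → co-regulated, same direction; any opposite
sign (or an exact within-genotype sign tie, under the default policy) →
co-regulated, opposite; DE in one genotype only → genotype-specific.
The tie policy is configurable (`tie_break="latest"` uses the sign at the
latest DE time point instead).

## Heat-tolerance phenotype

SFP = FSP/TSP × 100 per plant; summaries are the mean and *sample* standard
deviation over replicate plants (the ± column in published line tables is
taken as sd and labelled so).  HI is a **ratio of condition means**, which
reproduces published line-level values exactly (e.g. 55.8/66.4 → 0.84); a
paired mean-of-per-plant-ratios mode exists for uncertainty work.  HI's sd
is a delta-method propagation of the two standard errors.

## SSSL QTL mapping

Segment estimation follows the graphical-genotype dosage rule: a
marker-flanked span is 100% donor between two donor markers, 50% between a
donor and a recipient marker, 0% otherwise, giving

    length = span(DD) + ½·span(left DR) + ½·span(right DR).

The reported interval runs from the recipient marker before the first donor
marker to the recipient marker after the last one.  When a donor run
touches the first or last marker of a chromosome no recipient marker bounds
it; the default extends the interval to the chromosome end and counts that
terminal span fully (there is no recombination evidence against full donor
content there), with a `terminal="half"` alternative.

Testing: two-sample t-test of each line against the recurrent parent,
pooled variance by default (Welch optional), declared at raw p < 0.05 with
no across-line correction (an optional BH flag exists but is off, matching
single-line declaration practice in SSSL studies).  When the phenotype
table carries an `experiment` column with ≥ 2 levels, the default
(`replicate_unit="auto"`) runs the t-test **per experiment and declares a
QTL only when significant in every experiment**, reporting the maximum
p-value.  This consistency rule is how replicated SSSL field designs keep
the panel-wide false-positive load near zero (per-line null rate α³ ≈
1.3 × 10⁻⁴ instead of α = 0.05, which over ~20 null lines would otherwise
produce a spurious declaration in most panels); a single pooled test
remains available (`replicate_unit="pooled"`) and is what the null
type-I-error calibration test exercises.  Additive effects are
(line − parent)/2, averaged over experiments, with the percentage taken
against the experiment-averaged parent mean so that
`pct × parent_mean / 100 == effect` holds identically on every emitted
result.  QTLs are named `qHT-<chromosome>`, with `.2`, `.3` suffixes when
distinct segments on one chromosome are declared.

## Target complementarity scoring

The scorer is an in-repo reconstruction of the conventions plant target
predictors share, fully specified so results are reproducible without
external binaries: penalties mismatch 1.0, G:U wobble 0.5, gap 2.0,
doubled within miRNA positions 2–13 (the functionally critical 5′ region),
at most one gap (a bulged target base or an unpaired miRNA base) allowed
only 3′ of position 10, and sites reported at score ≤ 3.0 (a strict ≤ 2.0
mode mirrors tighter published cutoffs).  Scores are scheme-dependent and
outputs are flagged accordingly; a score of 0 is a perfect gap-free
antisense match.  A gap column is seed-weighted by the miRNA position it
sits at (for a target bulge, the position immediately 3′ of the insertion).
The search is exhaustive over every window and gap placement (vectorised
over window starts), reporting the best placement per (start, site length);
an independently written naive scorer in the test suite checks equality on
random sequences.  Cleavage is reported as the transcript coordinate
pairing miRNA position 11 (slicing occurs between the bases opposite
positions 10 and 11); with a gapped site the coordinate follows the actual
pairing, not the raw offset.  T and U are interchangeable on input.

## Integration and ranking

Gene loci and QTL intervals are intersected with any-overlap semantics on
0-based half-open megabase coordinates (a `containment` mode requires the
gene fully inside the interval).  Obvious chromosome-naming mismatches
between annotations (`chr8` vs `8`) raise rather than silently producing an
empty result.  Candidate (miRNA, gene, QTL) triples are dropped when the
miRNA has no DE evidence, when the gene's mean abundance is below the
expression floor (default mean TPM < 1 — the "not expressed" rule; the
threshold is configurable because published exclusions rarely state one),
or when the miRNA–gene Pearson r over matched (genotype, time point) cells
exceeds `r_max` (default 0: only anti-correlated pairs survive, the
signature of cleavage-based regulation; undefined correlations from
zero-variance profiles are dropped as undetermined).  Profiles are log₂
change relative to the time-matched control.  Survivors are ranked by
(r ascending, target score ascending) with ids as the final tie-break, so
output is invariant to input order.

## Coordinate and file conventions

Internal genomic coordinates are 0-based, half-open, in megabases (float) —
half-open arithmetic makes interval intersection trivial.  BED input is
read as 0-based half-open, GFF3 as 1-based closed; converters are exact
inverses within one base of rounding.  Gene annotation input is treated as
authoritative for its own assembly; no liftover is attempted.  All tables
are tab-separated UTF-8 with a header; `#` lines are comments.
Heterozygous genotype codes are rejected explicitly (SSSLs are fixed
lines), as are lines with more than one donor run.

## The synthetic-data generator

The generator's defaults are the study conditions the pipeline is designed
around, and are not tuned per test:

| parameter | default | rationale |
| --- | --- | --- |
| miRNAs / spiked | 200 / 20 | library-scale count table with a known heat-responsive subset |
| spike magnitude | &#124;log₂FC&#124; = 2, 25% up | four-fold responses; most heat-responsive miRNAs are repressed |
| library depth | 10⁶ reads | deep pooled sRNA libraries |
| dispersion φ | 0.1 (variance μ + φμ²) | standard overdispersion for pooled sRNA counts |
| panel | 23 lines, 12 chromosomes, 8 markers each | one-segment-per-line tiling |
| planted QTLs | chr 3/6/8/12, effects 3.59/5.60/9.24/2.72 | percent-scale effects of realistic magnitude, chromosome-matched |
| parent mean / noise sd | 18.5 / 1.5 (percent) | sensitive-parent stress fertility scale; sd gives near-full power at n = 10 |
| replication | 3 experiments × 10 plants | replicated field design |
| genes | 60, fraction of true targets in QTLs 0.5 | exercises both retention and exclusion |

Spiked miRNAs are drawn from the expressed stratum (baseline mean ≥ 100
reads), emulating confirmed miRNAs — a spike planted on a 3-read baseline
would be undetectable by any method and tests nothing.  Spikes follow a
staggered pattern: always in the first (tolerant-like) genotype from the
first or second time point, and with probability 0.4 in the second genotype
from a later onset — the tolerant genotype responds more and earlier, and
the cell-to-cell variation this creates is what makes miRNA–target
anti-correlation identifiable (a uniform spike across all six cells leaves
profiles constant and correlation undefined in practice).  True target
transcripts embed the reverse complement of their miRNA with 0–2 planted
mismatches outside the seed; two in-QTL targets are flagged unexpressed to
exercise the expression-floor exclusion.  Out-of-QTL genes are placed clear
of the carrier lines' full segment intervals, so the end-to-end assertion
"no candidate gene outside the QTL regions" is structural, not accidental.
All generators are pure functions of (config, seed) with one independent
substream per generator.

**What passing these tests shows — and does not.**  The synthetic data
match the analysis' own assumptions (negative-binomial counts, Gaussian
phenotypes, planted clean target sites, independent experiments).  Passing
therefore demonstrates correctness of the implementation and calibration
under those assumptions, not robustness to real-data pathologies: isomiR
ambiguity, mappability and cross-mapping artefacts, GC/length biases,
genotype-specific expression baselines, segregation distortion in the
panel, or target sites split across exons.  Headline counts from any real
study (hundreds of known miRNAs, ~100 DE calls, specific in-QTL gene
lists) depend on the deposited reads and genome annotation and are outside
desk-scale reproduction; the test suite covers them with the property-based
surrogates above (calibration, power, recovery, oracle equivalence,
end-to-end funnel recall).

## Problem sizes used by the default runs

The test suite and acceptance script size their simulations for a
single-CPU desk run: 20 null simulations × 1000 miRNAs for DE calibration,
the 200-miRNA default fixture for power, 10 panel repeats for exact QTL
recovery plus 100 panels for effect-error estimation, 100 random
miRNA/transcript pairs (≤ 500 nt) for scorer-oracle agreement, and one full
synthetic funnel.  All randomness derives from the provided seed.

## Known limitations

* Replicate-aware count models (edgeR/DESeq-style) are out of scope by
  design: the supported input is pooled libraries.
* The target scorer ignores site accessibility, free energy and
  translational inhibition; it is a complementarity filter.
* The anti-correlation filter uses as few as six condition cells; Pearson r
  at that size is a coarse screen, which is why it is a rank key and a sign
  filter rather than a significance test.
* Enrichment analyses (GO/PO/KEGG) of candidate targets are deliberately
  not included; the ranked candidate table is the package's endpoint.
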