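# Methods

This note documents the models and procedures implemented in `numt_atlas`,
the defaults that matter, and the choices made where several reasonable
designs existed. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and the circular mt genome

Internally every coordinate is 0-based half-open. SAM input (1-based) and
reported mtDNA positions (1-based inclusive, the convention of mt variant
databases) convert at the boundary. The mt contig is treated as circular
only where that matters: interval normalization (`normalize_mt_interval`
splits an origin-crossing interval into two linear parts and computes
lengths modulo the genome), circular distances for cluster merging, and the
control-region logic. Alignments themselves are taken as given on the
linearized contig, because short-read aligners produce linear placements.

## Detection model

A NUMT that is absent from the reference produces read pairs whose two
mates map to different contigs. Detection assumes:

* both junction-flanking sequences are uniquely mappable (MAPQ > 0 on both
  mates is required; MAPQ-0 alignments are parsed but discarded here, not
  at I/O time);
* discordant pairs from one insertion cluster within the library insert
  size; the clustering distance of **500 bp** on nuclear anchor starts is
  treated as a fixed parameter of the method;
* clusters never mix orientation signatures, where the signature is the
  (nuclear strand, mt strand) pair of the anchors — the standard convention
  for discordant clusters. The distance is measured start-to-start; the
  choice between starts, ends or footprints is not fixed by the method
  definition, and start-to-start is the simplest deterministic option.

Support thresholds: **2** discordant pairs for the sensitive call set,
**5** for the stringent set used in cohort statistics. Calls within
**1,000 bp on both genomes** (circular on mtDNA) merge by single linkage
with summed support. Single linkage was chosen because the grouping rule is
stated as a pairwise distance only; it is the weakest assumption and is
checkable against a brute-force transitive closure (done in the tests).
NUMTs longer than ~1 kb legitimately appear as two clusters (one per
junction) whose mt spans are farther than 1 kb apart; they remain two
candidates until breakpoint refinement ties them together.

## Breakpoint refinement and junction mechanism

Soft-clipped reads within 1,000 bp of a candidate (minimum clip **20 bp**)
have their clipped segment realigned by exhaustive local (infix) alignment
over both strands of the full mt genome plus the ±1,000 bp nuclear window.
A genome-scale seeded aligner is unnecessary at these search-space sizes;
the acceptance contract is explicit instead: aligned length ≥ 20 bp and
identity ≥ 90% (the edit-distance search is capped accordingly for speed).
Equal-best placements in more than one location make the read ambiguous and
it is dropped (counted, not silently lost).

Untemplated junction bases are recovered by trimming g junction-adjacent
bases from the clipped segment at a cost of one edit each and minimizing
total cost; among equal-cost solutions the placement with fewer residual
edits wins, attributing mismatching junction-adjacent bases to untemplated
insertion rather than alignment error. This is exact for error-free reads
and degrades gracefully: if inserted bases happen to match the reference
extension the junction is genuinely ambiguous and is reported blunt.

A breakpoint side needs **≥ 3** split reads; the position is the mode, ties
to the smallest coordinate (determinism). A candidate with two nuclear
positions each reaching the threshold is flagged complex rather than split.

Junction classes partition: **insertion** when untemplated bases are
present (modal gap string across supporting reads), else **microhomology**
when the nuclear flank and mt flank share ≥ 1 identical base across the
junction (scanned up to 30 bp, strand-aware), else **blunt**. The
breakpoint is reported at the mt-proximal end of the homology tract with
the homology length recorded, so a consumer can recover the full ambiguity
interval. Note that with a ~25% per-base chance match, short "microhomology"
arises at random junctions too; the classifier reports what the sequence
shows and leaves the null comparison to the enrichment machinery.

Sequence context around breakpoints: trinucleotides centred on the
breakpoint base (±1 bp) are tallied into 64 classes per side, reverse-
complemented for reverse-oriented inserts. The anchoring of the window on
the exact breakpoint base is a convention; the method's definition does not
pin it down, and centred ±1 bp is used throughout. Poly-C extension counts
breakpoints whose k ∈ {2,3,4} bases immediately beyond the mt breakpoint
(outside the insert; G on the minus strand) are all C, against an i.i.d.
mononucleotide null (N·f_C^k) with an exact binomial test. The i.i.d. null
is the simplest model consistent with "expected by chance" and is stated
openly; a positional or dinucleotide background would change the folds.

## Concatenated NUMTs

Reads clipped on the mt contig whose clipped segment realigns elsewhere on
mtDNA (best placement competed against every contig) mark internal
junctions of concatenated inserts. Observations collapse across samples
with a ±5 bp tolerance (realignment jitter; the collapse tolerance is a
package choice) and then pass, in order: ≥ 3 reads in at least one
individual; ≥ 2 reads per retained carrier; both positions outside the
D-loop terminus exclusion windows (defaults **1–100** and **16,470–16,569**;
the window width is configurable because true mtDNA and NUMT junctions
cannot be separated there); circular separation ≥ 50 bp (closer pairs may
be mtDNA deletions). The filters are independent per junction, so the final
set does not depend on their order (verified by permutation in the tests).

Transmission in trios: present in child and father but not mother →
father-transmitted; the converse → mother-transmitted; both parents,
neither, or child-only → indeterminate (child-only is additionally flagged
as candidate de novo). Presence in a parent is ≥ 1 split read — maximal
sensitivity, so de novo status is claimed conservatively.

## Cohort statistics

Cross-sample unification reuses the 1,000 bp/both-genomes single-linkage
rule. Representative coordinates are medians over members (refined
breakpoints preferred over cluster footprints), ties to the smaller
coordinate. Frequency F is carriers/individuals, one genome per individual;
duplicate genomes should be collapsed to the union of their calls before
unification. Classes: common F ≥ 1%, rare 0.1% ≤ F < 1%, ultra-rare
F < 0.1% — boundaries inclusive on the common side. "Private" means all
carriers belong to one family (singletons are their own family). "Known"
means a previously-reported NUMT interval overlaps the nuclear locus
± 500 bp, regardless of the mt fragment — deliberately permissive, since
reported NUMT fragments vary between catalogues.

## De novo, tumour-specific, and rates

De novo in a trio: child support ≥ 5; parental evidence re-checked down to
2 discordant pairs at the locus, and *any* parental discordant pair vetoes
(the primary rule demands none); finally the candidate's mt fragment must
have no second placement in the nuclear reference at ≥ 95% identity over
≥ 90% length — otherwise the apparent insertion could be a copy of existing
nuclear sequence. This uniqueness check is the desk-scale analogue of
realigning de novo assemblies genome-wide.

Tumour-specific: tumour ≥ 5 pairs, matched normal zero pairs; strict mode
additionally requires absence from every other genome in a supplied
background cohort. Lost: normal ≥ 5, tumour ≤ 1.

Rates are exact quotients with Clopper–Pearson 95% intervals (Beta-quantile
form; lower bound 0 at zero events, upper bound 1 at saturation). The
method reproduces the printed worked-example interval for 2/8,201 exactly,
which is how the interval form was confirmed. Note the published counts
around this rate are internally ambiguous (three events in two families
versus a rate implying two events per denominator); `insertion_rate` takes
the event count as given and does not resolve that ambiguity. The 2×2
carrier association uses the sample odds ratio (a·d)/(b·c), Fisher's exact
two-sided p by the probability-mass rule (tables as or less probable than
observed; the doubling rule is a documented alternative), and a
normal-approximation CI on the log odds ratio with Haldane 0.5 correction
flagged when a cell is zero.

## Permutation enrichment

Observed = NUMTs whose ±100 bp flank intersects the track. Null = 1,000
replicates placing the same number of points uniformly on the same
chromosome as each observed NUMT ("matched" = count + chromosome; flanks
are fixed-width so no length matching is needed; chromosome matching
preserves large-scale composition). The Y chromosome and the mt contig are
excluded from nuclear placements. Two-tailed p = min(1, 2·(1 + #as-or-more-
extreme)/(N + 1)): the add-one rule keeps p ≥ 2/(N+1) and the cap keeps it
≤ 1; the estimator is slightly conservative, which the calibration test
quantifies. mtDNA-region enrichment uses the same contract with uniform
circular placement; region coordinates ship as configuration data
(standard human mt annotation conventions) and are user-overridable. The
deletion-breakpoint comparison bins both breakpoint sets into fixed 100 bp
windows (166 on a 16,569 bp genome) and reports the Pearson correlation of
per-window frequencies. The chromosome-count regression is OLS of
per-chromosome NUMT counts on chromosome length plus eleven log2 feature
proportions, with an explicit rank check that names collinear columns. The
simulated genomes contain no assembly gaps; a gap mask for null placements
is therefore unnecessary here and real-genome users should mask gaps
upstream.

## Consensus, variants, spectra, ages

Reads attributable to one NUMT in one sample are the mt-side mates of its
discordant pairs (soft-clipped tails trimmed — they belong to the nuclear
flank or a neighbouring segment) plus realigned clipped pieces of
junction-spanning reads, all oriented to the mt forward strand. Assembly is
greedy overlap-layout-consensus: repeatedly merge the contig pair with the
longest exact suffix–prefix overlap ≥ **25 bp**, ties to the
lexicographically smaller merged string; the final base per column is the
majority over contributing reads, an exact tie resolving to the reference
base at the aligned position. Exact-overlap merging is adequate for
error-free to low-error reads at desk scale; with no overlap the longest
contig is returned flagged fragmented. Coverage per assembly is capped at
60 reads (deterministic subsample) to bound cost.

Variant filter cascade, in order: NUMT < 1,000 bp; variant > 5 bp from both
mt breakpoints; reference-allele concordance; SNVs only; per-sample outlier
exclusion (count > cohort mean + 3 s.d., zero-variant samples included in
the background); removal of the standard mt low-complexity tracts (66–71,
300–316, 513–525, 3106–3107, 12418–12425, 16182–16194). The low-complexity
exclusion is borrowed from mtDNA variant-calling practice because the same
alignment artefacts affect NUMT consensus alignment; it is toggleable.
NUMT-specific groups: A removes alleles in > 50% of carriers of a
common/rare NUMT (> 75% for ultra-rare — those likely predate insertion);
B removes singletons; C keeps variants seen in ≥ 2 members of one family.
C ⊆ B ⊆ A by construction.

Coding effects use the vertebrate mitochondrial genetic code, strand-aware
codon lookup from the packaged region table. Spectra are the standard 96
pyrimidine-centred trinucleotide classes; purine-reference variants are
reverse-complemented. Cosine similarity against a user-supplied 96 × k
signature matrix is available; no signature catalogue is shipped.

Ages: across sites where the human and ancestral mt sequences differ within
the fragment, r = fraction carrying the human allele, and
**age = (1 − r) × 6 Myr** against a 6 Myr human–chimpanzee divergence. The
linear transform follows from mutations accruing uniformly on the human mt
lineage — sites that diverged after insertion retain the ancestral state in
the NUMT. r is computed per site with majority agreement across carriers
(> 50% of carriers, ≥ 2 carriers must agree; disagreeing or non-matching
sites are dropped), an aggregation chosen over a pooled cohort consensus
because it is robust to one bad assembly. Eligibility: fragment 50–1,000 bp,
≥ 1 informative site, not concatenated.

## The synthetic cohort generator

The generator is first-class, tested code. It emulates exactly the
statistical structure the analysis consumes:

* donor haplotypes = nuclear contigs with mt-derived inserts spliced in;
  microhomology splices count shared bases once (the splice point moves to
  the nearest position carrying the required homology and the realized
  position is recorded in the truth), insertion junctions add untemplated
  bases;
* uniform fragment sampling at **30×** mean depth, **150 bp** paired-end
  reads, insert length ~ Normal(**400**, **60**) bp truncated at one read
  length — representative short-read WGS parameters;
* alignment is emulated, not run: each read is placed at the position
  implied by its donor block, junction-spanning reads become soft-clipped
  records clipped exactly at the junction, and mates anchored across an
  insert become nuclear–mt discordant pairs. MAPQ is 60 everywhere except
  configured decoy regions (MAPQ 0), which exist to exercise the mapping-
  quality filter;
* post-insertion evolution: explicit planted SNVs, and age-driven reversion
  — at sites where the synthetic ancestral mt (default 8% divergence, so
  short fragments contain informative sites) differs from the mt reference,
  the insert carries the ancestral allele with probability `age_fraction`,
  one realization per NUMT shared by its carriers. Expected estimated age
  is therefore `age_fraction × 6 Myr`;
* machine-readable truth (coordinates, junction spec, realized reversion
  sites, carriers with de novo / tumour-specific flags, seed and all
  parameters) and a sample manifest.

Everything is a pure function of (design, seed); the same seed yields
byte-identical SAM output.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: sequencing errors are off by default
(optional uniform substitution rate only), no indels in reads, no coverage
waves or GC bias, no contamination, haploid donors (a heterozygous carrier
in a diploid genome would halve junction support), no reference NUMTs, no
alignment ambiguity beyond the explicit decoy list, and a uniformly random
nuclear background rather than real repeat structure. Detection performance
on real genomes is bounded above by the clean-simulation numbers.

## Packaged reference data

The bundled mt reference (`data/synthetic_rcrs.fa`) is a **synthetic
stand-in** — a deterministic random 16,569 bp sequence with a roughly
mtDNA-like base composition — not the real human mt sequence, which is not
redistributed here. The ancestral mt sequence is likewise generated, not
real. All entry points accept user-supplied FASTA files for both, and the
mt region table is configuration data replaceable by the user. Analyses
that depend only on coordinates, counts and the generative model (that is,
everything this package computes on simulated cohorts) are unaffected by
the stand-in; sequence-specific biology (real poly-C tract positions, real
codon content) requires the real references.

## Problem sizes

Test and benchmark cohorts are desk-scale by design: contigs of 20–350 kb,
cohorts of 2–150 samples, 30× depth. The benchmark scenarios in
`numt_atlas.scenarios` state their sizes in their docstrings; together they
run in about a minute on one core.

## Known limitations

* Breakpoints inside long perfect repeats shared by nuclear and mt genomes
  are reported as ambiguous rather than resolved.
* The greedy exact-overlap assembler cannot place reads that disagree with
  every overlap partner (e.g. a 50% within-sample variant with no clean
  flanking overlap); such reads end up in fragmented side-contigs.
* Concatemer internal structure beyond pairwise junctions (full copy
  number, segment order) is out of scope.
* The per-individual age aggregation discards sites where carriers
  disagree, which biases ages slightly toward well-covered sites.
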