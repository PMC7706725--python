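# Methods

This note records the models, defaults, and design choices behind
`trapsplice`, and what the synthetic studies do and do not establish.

## PSI over splice-site sharing groups

A junction's donor-side PSI is its read count divided by the summed
counts of all junctions sharing its donor site in the same pooling unit;
the acceptor side is analogous. A side is left undefined when its group
total is below `min_group_reads` (default 10 reads per pooled unit): at
lower totals the ratio estimate is too noisy to report. The two sides
are summarized as their minimum — the conservative choice when donor and
acceptor groups disagree; the schema defines both sides but no
combination rule, so the summary rule is this package's own. Replicates
are pooled by summing counts rather than averaging per-replicate PSI,
which weights replicates by their information content and is stable at
low counts.

Tissue-enriched junction detection requires summed IP support at or
above the threshold (a `strict` flag switches to a strict inequality,
matching the two wordings "at least five reads" and "more than 20
reads") and *exactly zero* reads across all whole-animal input samples;
a `per_replicate` flag instead requires each IP replicate to pass
individually. Alternative splice-site groups are those with ≥2 defined
members whose minor member reaches `minor_psi_min` (default 0.05) in at
least one tissue.

Down-sampling for saturation analysis thins every count binomially,
which is exactly what resampling reads without replacement approximates
at typical depths.

## Splice graphs and event classification

Nodes are exonic segments: the union of transcript exons split at every
splice-site boundary, including boundaries introduced by observed
junctions landing mid-exon. Edges are junctions (annotated junctions are
always included; observed junctions matching no boundary are recorded as
orphans and excluded) and, when intronic read support is supplied,
intron-retention edges. Retention is never inferred from coverage
profiles here; it requires explicit intronic counts.

A local splicing variation (LSV) is the set of ≥2 edges leaving one
node's 3′ side (source) or entering one node's 5′ side (target);
identical edge sets are emitted once. Classification tests fixed
templates in a fixed order:

1. **cassette** — two junctions from one anchor to a near internal
   segment E and a far segment D, with the E–D junction present;
2. **alt 3′/5′ splice site** — two junctions whose distal segments are
   contiguous (adjacent segments of one exon); source events vary the
   acceptor (alt3ss), target events the donor (alt5ss), which makes the
   subclass strand-correct by construction;
3. **mutually exclusive** — two internal distal exons, no junction
   between them, both splicing to a common partner that the anchor does
   not reach directly;
4. **alternative start/terminal** — all distal segments are annotated
   first (last) exon segments and are not contiguous with each other
   (contiguous segments are an alternative-splice-site pattern, not
   distinct terminal exons);
5. **intron retention** — a junction edge and a retention edge over the
   same intron.

An event matching exactly one template gets that class; matching several
templates, or matching none, yields `complex`. The "matching-none ⇒
complex" catch-all extends the multi-mode definition to ambiguous
two-junction events; it never fires on the implanted canonical classes
in the synthetic studies.

Event PSI is the empirical count ratio per tissue (junction count over
the event total, retention edges contributing intronic counts),
undefined below `min_event_reads` (default 10, a conventional
quantifiability floor). This is deliberately an empirical ratio, not a
Bayesian posterior: the package re-implements the junction-centric
analysis with transparent arithmetic. ΔPSI is computed on the event's
reference junction — the edge with the largest read total across
quantified tissues, ties broken lexicographically — because a
multi-junction event has no single canonical ΔPSI otherwise. Threshold
flags use a 1e-9 tolerance so exact-threshold effects do not flip on
float rounding. Default thresholds: 0.20 differential, 0.80
switch-like, with 0.15 available where a more permissive gene set is
wanted.

The class-proportion comparison is a 2×2 Pearson chi-squared (one class
versus the rest, no continuity correction, df = 1). The
expression-versus-splicing decoupling analysis computes per-gene log2
fold change over the cross-tissue median with pseudocount 1, flags genes
differentially expressed at a max/min count ratio ≥ 5 (only genes
reaching 50 reads somewhere), and reports the Spearman correlation
between expression-difference magnitude and |ΔPSI|.

## Exon triplets and conservation

Cassette events supply alternative triplets (tissue-regulated when any
differential call flags the event); constitutive triplets are annotated
internal exons overlapping no event whose four flanking splice sites are
each used by exactly one junction. A triplet is conserved in a species
when all three exons are present — at least `exon_presence_min` (0.5) of
each exon's reference columns carry non-gap species characters — and the
four internal splice sites align: species non-gap characters at both
intron-terminal reference columns, exact columns by default
(`splice_site_window` 0). A `require_canonical` flag additionally
demands the GT/AG dinucleotides themselves; it defaults off because the
criterion as defined rests on alignment, not sequence identity. The 0.5
presence threshold and exact-column site rule are this package's
operationalization; the criterion's ingredients (exon presence, site
alignment) come from the analysis being reproduced, which states no
thresholds.

The built-in aligner is a center-star multiple aligner over pairwise
global (Needleman–Wunsch) alignments with affine gaps: match +1,
mismatch −1, and a gap of length L scoring −2 − 0.5·L, all
configurable; traceback prefers diagonal, then up, so results are
deterministic. A built-in aligner keeps the artifact free of external
binaries. Rate comparisons use a two-sided Fisher exact test implemented
by exact shared-denominator enumeration with integer tie comparison
(`fisher_exact_two_sided`); it matches `scipy.stats.fisher_exact` and is
fast enough to be verified against brute-force enumeration over every
2×2 table with total ≤ 60.

Window profiles cover the first/last `flank_len` = 23 intronic bases at
each of the four intron ends (position 1 = first intronic base from the
splice site, strand-aware), smoothed with a centered rolling mean of
window 3 truncated at the edges; 23 still splits the smallest (~40-nt)
introns into halves. Introns shorter than 2·flank contribute their
available positions and are flagged. Class comparisons are reported two
ways: a Wilcoxon signed-rank paired over the 23 position means (the
default; the named test's pairing unit is not stated upstream, so
pairing by position is declared here), and an unpaired Mann–Whitney
rank-sum over per-event mean scores.

## Exon features

Frame preservation is length mod 3 = 0. Microexons are ≤27 nt
inclusive (the stricter "<27" reading is available via a flag).
Exon-to-protein mapping walks the transcript CDS in translation order,
checks GTF-style phase consistency, and converts the exon's coding
overlap to 1-based amino-acid coordinates (aa_start = ⌊offset/3⌋+1,
aa_end = ⌈(offset+len)/3⌉), attributing codon-spanning exons to every
amino acid they touch. Domain/IDR overlap means ≥1 shared amino acid
against user-supplied intervals; records whose protein lacks annotation
are excluded from denominators by default. Disorder prediction and
domain assignment are inputs, never computed.

## K-mer enrichment

Scoring is presence/absence per sequence (zero-or-one occurrences), the
display convention of percent-of-targets versus percent-of-background:
p is the hypergeometric tail probability of drawing at least the
observed number of containing sequences into the target set from the
pooled population. Correction (Benjamini–Hochberg default, Bonferroni
optional) is applied per k over all 4^k words. No PWM building, no
degenerate positions, no GC-matched background generation — the
background set is always supplied by the caller (typically non-regulated
event regions).

## Synthetic data: what it emulates and what it does not

The generator lays out 200 genes (3–8 exons, exons 75–150 nt, introns
60–100 nt with canonical GT..AG termini on the coding strand, both
strands represented) on one chromosome and implants one event per event
gene: 40 cassette (half tissue-regulated, ΔPSI 0.7 by default, four of
them microexons of 6/15/21/27 nt), 10 each alt5ss/alt3ss/intron
retention, 8 each mutually exclusive and alternative start/terminal, 6
multi-mode (complex) regions.

Counts follow the study design: five tissues (three broad at whole-animal
fractions 0.26/0.30/0.40, two neuronal subtypes at 0.02 each), two IP
replicates per tissue and two whole-animal input replicates. Per event,
tissue, and replicate, a Poisson event total (expected `depth` = 200)
is split across isoform paths by a Dirichlet-multinomial around the true
Ψ with dispersion ρ = 5e-4 — library replicates of the same biological
pool vary by a few percent, so dispersion is small. Constitutive genes
draw log-uniform depths from 300–800. Input samples see each junction at
`input_rate_ratio` = 0.01 of its whole-animal mixture rate: TRAP IP
enriches a tissue's ribosome-associated transcripts by roughly two
orders of magnitude over their whole-animal representation, which is
what makes a subtype junction with hundreds of IP reads expect well
under one input read while housekeeping-level genes remain solidly
covered in input. The dedicated dilution study config uses 60
subtype-exclusive genes at IP depth 100 against 60 shared genes at
depth 500–1000 to measure detection sensitivity and specificity under
exactly that regime.

Phylogeny simulation evolves each triplet region per species with
per-branch substitution and geometric-length indel processes, atomic
internal-exon loss (truth label: not conserved), halved loss probability
and 10× protected splice-site dinucleotides for tissue-regulated
triplets. The emitted MAF blocks are the true alignments from the known
edit history. Conservation tracks are N(0,1) per base with +δ (default
2.0) added within 23 nt of regulated exons' splice sites; protein
domain/IDR intervals are placed to hit configured per-class overlap
rates (IDR 0.30/0.55/0.80 for constitutive / alternative /
tissue-regulated).

What passing on this generator shows: the estimators recover known
truth under the design's statistical structure (dilution, replicate
noise, branch-dependent divergence, implanted regulatory signal). What
it does not show: robustness to misannotation, unannotated junction
discovery from alignments, non-canonical splice sites, overlapping
genes, coverage-dependent biases within transcripts, or realistic codon
evolution — real data carry all of these and the synthetic genome
carries none.

## Numerical and determinism choices

All randomness flows from one integer seed through
`numpy.random.default_rng`; annotation, counts, phylogeny, and tracks
use separate seed streams spawned from it, so each stage is reproducible
in isolation. Event tables, TSVs, and the pipeline report are
deterministic (fixed template order, lexicographic tie-breaks, fixed
float formatting); the pipeline manifest records SHA-256 digests and a
re-run with an identical manifest recomputes nothing. The acceptance
script runs every analysis at sizes that keep the whole sweep under a
minute on one CPU: 500 random tables for the PSI oracle, 200-gene
studies for recovery, 210 triplets for conservation, 200 replicates for
null calibrations, 20 seeds for enrichment power.

## Known limitations

- PSI carries no uncertainty intervals; low-coverage gating is the only
  noise control.
- The classifier sees only one gene's graph at a time; events spanning
  gene boundaries (fusion, readthrough) are out of scope.
- Intron retention requires externally supplied intronic counts.
- The center-star aligner is quadratic per pairwise alignment and meant
  for triplet-scale regions, not chromosomes.
- The constitutive-triplet rule is conservative: exons of genes with any
  nearby event are excluded entirely.
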