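# Methods

## The analysis in outline

The pipeline characterises cassette-exon (and intron-retention)
splicing events that respond to knockdown of EJC core proteins
(eIF4A3, Y14, MLN51; Upf1 serves as an NMD-pathway comparator). It
takes differential-splicing calls from two complementary callers, an
annotation, a genome, CLIP and mRNA coverage, and per-gene read counts;
it emits a categorized event catalog, per-event sequence features with
group statistics, positional CLIP profiles, and AS-NMD flags.

ΔΨ is defined as Ψ_control − Ψ_knockdown throughout, so ΔΨ > 0 means
increased skipping (for intron events: increased splicing of the
intron) in the knockdown. A direction label requires strict
|ΔΨ| > 0.1 in at least one of the three EJC contrasts; significance in
"EJC knockdown" is the union over the three contrasts.

## Event catalog

**Caller filters.** The exon-centric caller is filtered per replicate
with five simultaneous strict thresholds: |ΔΨ| > 0.1, evidence score
("Bayes factor") > 5, inclusion reads > 10, skipping reads > 10,
inclusion + skipping > 20. An event survives a contrast only when it
passes in both replicates at identical coordinates with the same ΔΨ
sign; the reported ΔΨ and Ψ are replicate means, the evidence score the
smaller of the two (conservative), counts are summed. The splice-graph
caller is replicate-aware; its events pass at |ΔΨ| > 0.1 and
√JSD > 0.1, and their cassette-exon coordinates are resolved from the
annotation because the caller reports only the flank boundaries.

**Merging.** The union of the two catalogs is deduplicated by cassette
exon coordinates (chromosome, strand, start, end) — the only identity
the two callers share. When both report an event, ΔΨ comes from the
exon-centric caller (its estimates are read-count-based rather than
graph-flow-based); coordinate-equal events with opposite signs are
discordant: excluded from categories but retained in the audit table.

**Classification and exclusions.** Events are categorized only when the
cassette exon and both flanks are present in the annotation, both
flanks are constitutive, no other alternative exon falls within the
event span, and no other event's cassette exon overlaps — the
complex-splicing-pattern exclusions. ALT means the cassette exon is
annotated alternative; CON means it has no alternative annotation
(defective splicing of a normally constitutive exon).

**Controls.** Ctr: alternative events with |ΔΨ| < 0.03 in every EJC
contrast (replicate-averaged) and all Ψ estimates inside the open
interval (0.1; 0.9), from expressed genes, sampled without replacement
to the requested size (a parameter, not a constant). CtrCON: trios of
successive constitutive exons, excluding first/last transcript exons,
at most one trio per gene. Requesting more than the eligible pool
returns the pool with a warning.

**Expression filter.** Coverage C = R·N/L with read length R (default
51 nt), gene read count N and transcript length L. A gene is expressed
when C ≥ 10 (inclusive, so the worked value C = 10.0 passes) in the
control and in at least one knockdown. Fold changes are
total-count-normalised ratios N_KD/N_control.

## Splice-site models

The default model is an independent per-position nucleotide probability
model with a global background; score(s) = Σᵢ log₂(Pᵢ(sᵢ)/q(sᵢ)) in
bits. Donor sites are 9-mers (3 exonic + 6 intronic nt), acceptor sites
23-mers (20 intronic + 3 exonic nt). Training uses an additive
pseudocount (default 0.5); the background defaults to the global
composition of the training set. A model whose per-position rows equal
its background scores exactly 0 for every sequence, anchoring the
scale. The published maximum-entropy score tables can in principle
substitute for this model, but they are not redistributable with the
package; `load_site_models` reads the package's own plain-text
serialization and points users to `train_site_model` otherwise. In the
pipeline the models are trained on all junctions of the supplied
annotation.

## Splicing-regulatory elements

Frequencies are occurrences per nucleotide: the number of sliding
windows whose k-mer belongs to the set (overlaps all counted — a
documented choice; the convention affects absolute frequencies but not
group contrasts), divided by the sequence length. Exonic sets (ESE,
ESS) are evaluated over whole exons, intronic sets (ISE hexamers, ISS
decamers) over whole flanking introns, with no sub-window. The bundled
motif files are synthetic stand-ins with realistic set sizes
(238/176/199 hexamers, 102 decamers); real screens' motif lists can be
dropped in as one-motif-per-line text files.

The enrichment z-score compares the observed frequency with 100
seeded shuffles of the same sequence: z = (f_obs − mean f_shuf)/sd
f_shuf. The default shuffle is a uniform permutation of nucleotides
(mononucleotide composition preserved); a dinucleotide-preserving
Eulerian-walk shuffle is available behind `shuffle="di"`. When every
shuffle gives the same frequency (sd = 0, e.g. homopolymers) the result
is the NaN sentinel, never ±∞, and such values are excluded from
downstream summaries rather than imputed. Under the null the z-scores
are close to standard: over 500 random 300-nt sequences against a
40-hexamer set the acceptance script measures mean ≈ 0 and sd ≈ 1.03
(slightly above 1, as expected when standardising by a 100-sample sd).

## RNA splicing maps

For each category of exons, windows of 100 nt are anchored at both
borders of the upstream, cassette and downstream exon (exons shorter
than 200 nt keep both full frames, so their positions appear in both —
short exons are not discarded). Per position, CLIP coverage is divided
by mRNA coverage (positions with zero mRNA are masked, not
pseudocounted, avoiding unbounded ratios; n(p) counts only unmasked
contributions — masking before counting is the declared resolution of
an ambiguity); heights are the per-position mean over exons, then the
whole category profile is divided by its maximum over the analysed
region, so max = 1. This order — per-exon ratio, per-position mean,
global max-scaling — makes the profile invariant to per-gene
expression level, to any rescaling of the CLIP library, and to
category size. Intron maps use the same machinery with windows on the
intronic side of the cassette-exon borders.

## NMD and AS-NMD

A stop codon is premature when it lies strictly more than 50 nt
upstream of the last exon–exon junction, in spliced-transcript
coordinates ("upstream of an EJC" operationalised as the standard
50-nt rule; the boundary is strict: 50 → not premature, 51 →
premature). Single-exon transcripts are never PTC+. The skipping
isoform of an event is derived from the inclusion transcript by
removing the cassette exon and re-scanning from the same CDS start for
the first in-frame stop (the source analysis does not describe its ORF
handling; this is the package's choice). An event is PTC-bearing when
either isoform is PTC+, and an AS-NMD candidate when additionally the
gene's mRNA fold change exceeds 1.5 (strict) in at least one EJC
knockdown; missing fold changes give "undetermined", never silent
drops.

## Synthetic data: what it emulates, and what it does not

The generator fixes the study conditions; its defaults are chosen once:

- Genes of 5–9 exons; exon lengths lognormal (median ≈ 120 nt), intron
  lengths lognormal (median ≈ 665 nt — below the human genome-wide
  median so that simulated genomes stay compact; the analyses tested
  here depend on relative, not absolute, intron lengths). Donor/acceptor
  contexts are sampled from canonical-like position models and embedded
  at every junction.
- 30% of internal exons are cassette exons; 30% of cassette events are
  affected, with |ΔΨ| = 0.3 in the three EJC contrasts, 65%
  skipping-up / 35% inclusion-up (the observed direction split in EJC
  knockdowns); control Ψ uniform in (0.35, 0.65). In ~8% of genes an
  unannotated constitutive exon additionally changes (all skipping-up),
  detected only by the splice-graph caller — the CON class.
- Informative read totals are Poisson at depth 100 per replicate;
  inclusion reads binomial at the true Ψ (optional beta-binomial
  overdispersion behind a flag; off by default, matching the filters
  under test). The evidence score standing in for the caller's Bayes
  factor is 2·|ΔΨ̂|·√(total reads) — monotone in effect size and depth
  so the published threshold of 5 separates planted from null events at
  the default depth; the caller's actual Bayesian machinery is out of
  scope.
- CLIP coverage is background 2 plus a Gaussian peak of height 20
  (peak/background = 10) centred 24 nt upstream of each exon's 3′
  border, scaled by the gene's expression; mRNA coverage is uniform per
  exon at a lognormal per-gene level (median 30). Peaks falling outside
  short exons are truncated with a warning.
- Inclusion-isoform reading frames are kept open (chance in-frame stops
  recoded), the stop codon sits in the last exon, and 35% of cassette
  exons have lengths that are not multiples of 3, so their skipping
  isoforms frameshift into an early stop — the PTC+ events. Genes with
  a PTC+ skipping isoform are up-regulated 2-fold in EJC knockdowns
  with probability 0.5, emulating stabilised AS-NMD targets.

A fixed seed yields byte-identical output files; independent
deterministic substreams drive annotation, event sampling, coverage and
counts.

The generator does **not** emulate: read-level artefacts (mapping
bias, positional coverage decay), isoform-resolution quantification
uncertainty beyond binomial sampling, correlated replicates, 5′/3′
alternative splice sites, non-canonical CLIP peaks, or sequence-driven
splicing (planted motifs do not influence the simulated Ψ). Passing
tests therefore demonstrate that the analysis code implements its
definitions correctly and recovers planted signal under the stated
noise model — not that the biological conclusions would replicate on
real libraries.

## Numerical and design choices

- Coordinates are 0-based half-open internally; GTF is 1-based
  inclusive at the boundary; TSV event tables use the internal
  convention. Parsing uses round-trip float precision so
  write→parse is lossless.
- All caller thresholds are strict (>) as printed; the expression
  coverage threshold is inclusive (≥) so its printed example value
  passes.
- Replicate ΔΨ are averaged on intersection (keeping the larger value
  is the alternative; averaging is declared and oracle-tested).
- Group tests use the Mann–Whitney–Wilcoxon two-sided test, exact for
  small tie-free samples and normal-approximated otherwise; p-values
  across feature families are reported raw and BH-adjusted.
- Spearman correlations use tie-corrected ranks; constant inputs give
  the NaN sentinel.
- Problem sizes in the test-suite and acceptance script (150–220 genes,
  ~1000 events, 20 map-recovery replicates, 500 null sequences) were
  chosen so every distributional check has comfortable statistical
  margin at the default effect sizes.

## Known limitations

- The splice-graph caller's coordinate resolution requires the cassette
  exon to be identifiable from the annotation; events in unannotated
  regions are audited, not recovered ab initio.
- A5SS/A3SS event classes are out of scope; intron retention is
  supported at the parsing/classification level only.
- The AS-NMD flag uses gene-level fold changes; isoform-level
  quantification would be sharper but is not an input of this analysis.
- Whether the source analysis considered all annotated isoforms or only
  the two event isoforms for PTC prediction is unstated; this package
  evaluates the two event isoforms.
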