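# ejcsplice

Analysis pipeline for characterising splicing events that depend on the
exon junction complex (EJC) — the eIF4A3/Magoh/Y14/MLN51 core deposited
~24 nt upstream of exon–exon junctions on spliced mRNAs. Knocking down
EJC core proteins in human cells changes the inclusion of hundreds of
cassette exons; this package implements the downstream computational
analysis of such knockdown mRNA-seq experiments, for researchers
studying splicing regulation:

- **Event catalog** — parse differential-splicing calls from two caller
  dialects (an exon-centric per-replicate caller reporting Ψ and a
  Bayes-factor-like evidence score, and a replicate-aware splice-graph
  caller), apply the significance filters (|ΔΨ| > 0.1, evidence > 5,
  inclusion reads > 10, skipping reads > 10, inclusion + skipping > 20,
  all strict), intersect replicates, merge the two catalogs, and label
  each event by direction (ΔΨ = Ψ_control − Ψ_KD; "+" = skipping up in
  the knockdown) and annotation class (ALT = annotated alternative exon,
  CON = constitutive). Control sets: alternative exons without changes
  (|ΔΨ| < 0.03, Ψ ∈ (0.1; 0.9)) and trios of successive constitutive
  exons. Genes pass an expression filter with coverage
  C = read length × reads / transcript length ≥ 10.
- **Sequence features** — flanking intron/exon lengths; splice-site
  strength as per-position log-odds scores in bits over the standard
  9-mer donor window (last 3 exonic + first 6 intronic nt) and 23-mer
  acceptor window (last 20 intronic + first 3 exonic nt); frequencies of
  splicing-regulatory elements (ESE/ESS hexamers in exons, ISE hexamers
  and ISS decamers in introns) per nucleotide; permutation z-scores
  against 100 composition-preserving shuffles; Mann–Whitney–Wilcoxon
  group comparisons and Spearman correlations.
- **RNA splicing maps** — positional CLIP-binding profiles over 100-nt
  windows at exon borders: CLIP coverage normalised per position by
  mRNA coverage and by the number of contributing exons, then scaled to
  a maximum of 1 per category.
- **NMD flags** — the 50-nt rule (a stop codon is premature when it
  lies more than 50 nt upstream of the last exon–exon junction) and
  AS-NMD candidate flagging (PTC-bearing event whose total mRNA rises
  > 1.5-fold in an EJC knockdown).
- **Synthetic data** — a fully seeded generator producing gene models,
  genome sequence with embedded splice-site contexts, binomially
  sampled inclusion/skipping counts at known true Ψ, CLIP coverage with
  a planted −24 nt peak, and per-gene read counts, so every stage runs
  and is testable with no downloads.

## Worked example

Simulate a 50-gene experiment and run every stage:

```
$ ejc-splice run-all --seed 5 --outdir demo
n_asnmd_candidates      4
n_categorized   19
n_ctr   6
n_ctr_con       31
n_expressed_genes       50
n_inclusion_up  5
n_merged        29
n_ptc_bearing   8
n_skipping_up   14
pct_asnmd_of_ptc        50.0
pct_ptc_bearing 42.10526315789474
pct_skipping_up 73.6842105263158
seed    5
```

Of the 29 merged significant events, 19 survive classification (the
rest have non-constitutive flanks or complex splicing patterns); 14 of
the 19 (74%) increase in skipping under EJC knockdown, 8 carry a
premature stop in one isoform, and 4 of those also rise > 1.5-fold in
mRNA level — the AS-NMD candidates. `demo/` contains the categorized
event table, the per-event feature table with Mann–Whitney group tests
(raw and BH-adjusted p), the splicing-map profiles (which peak at
−24 nt from the exon 3′ border, the canonical EJC deposition site), the
NMD flags, per-category counts:

```
direction  annot_class  count  percent
+          ALT          11     57.9
+          CON          3      15.8
-          ALT          5      26.3
-          CON          0      0.0
```

and `run.log`, which records the exact predicate of every filter
applied together with the seed. The same `run-all` invocation with the
same seed reproduces the bundle byte for byte.

The library surface mirrors the stages: `ejcsplice.catalog`
(`parse_event_table`, `filter_miso_events`, `intersect_replicates`,
`merge_catalogs`, `classify_events`, `build_controls`,
`expression_filter`), `ejcsplice.features` (`train_site_model`,
`score_site`, `sre_frequency`, `motif_zscore`, `compare_groups`),
`ejcsplice.splicemap` (`build_map`, `build_intron_map`),
`ejcsplice.nmd` (`find_ptc`, `asnmd_candidates`) and
`ejcsplice.synthetic` (`SimConfig`, `generate_annotation`, …).

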