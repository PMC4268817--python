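"""End-to-end orchestration: simulate (or load) inputs, build the event
catalog, compute sequence features with group statistics, draw splicing
maps, flag AS-NMD candidates, and write a deterministic report bundle.

Every threshold applied is logged with its predicate text, and all
randomness flows from the configured seeds, so a fixed configuration
reproduces the bundle byte for byte.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import false_discovery_control

from . import catalog as cat
from . import features as feat
from . import nmd
from . import splicemap
from .annotation import GenomeAnnotation, read_fasta, write_fasta
from .synthetic import SimConfig, generate_annotation, simulate_coverage, \
    simulate_event_tables, simulate_expression_counts
from .tracks import CoverageTrack


class PipelineInputError(ValueError):
    """Bad configuration or missing input file (CLI exit code 1)."""


@dataclass
class Thresholds:
    """All printed analysis thresholds in one place."""

    delta_psi: float = 0.1        # |dPsi| > t, strict
    evidence: float = 5.0         # caller evidence score > t, strict
    min_inclusion: int = 10       # inclusion reads > t, strict
    min_skipping: int = 10        # skipping reads > t, strict
    min_total: int = 20           # inclusion + skipping > t, strict
    coverage: float = 10.0        # expression coverage >= t, inclusive
    fold_change: float = 1.5      # AS-NMD mRNA fold change > t, strict
    ctr_max_delta: float = 0.03   # control-set |dPsi| < t in every EJC contrast
    ctr_psi_low: float = 0.1      # control-set Psi in the open interval
    ctr_psi_high: float = 0.9
    n_shuffles: int = 100         # z-score randomisations
    window: int = 100             # splicing-map border window, nt

    def __post_init__(self) -> None:
        for name in ("delta_psi", "evidence", "coverage", "fold_change",
                     "ctr_max_delta", "n_shuffles", "window"):
            if getattr(self, name) <= 0:
                raise PipelineInputError(f"threshold {name} must be positive")


@dataclass
class PipelineInputs:
    annotation_gtf: str | None = None
    genome_fasta: str | None = None
    miso_tables: dict[str, str] = field(default_factory=dict)  # "contrast:rep" -> path
    diffsplice_table: str | None = None
    clip_bedgraph: dict[str, str] = field(default_factory=dict)    # strand -> path
    mrna_bedgraph: dict[str, str] = field(default_factory=dict)
    counts_tsv: str | None = None


@dataclass
class PipelineConfig:
    simulation: SimConfig | None = None
    inputs: PipelineInputs | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_ctr: int = 150
    n_ctr_con: int = 150
    seed: int = 0
    outdir: str = "ejcsplice_out"

    def __post_init__(self) -> None:
        if self.simulation is None and self.inputs is None:
            raise PipelineInputError("config needs a simulation block or input paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = _simconfig_from_dict(dict(raw["simulation"])) if isinstance(
            raw.get("simulation"), dict) else None
        inputs = PipelineInputs(**raw["inputs"]) if "inputs" in raw else None
        thresholds = Thresholds(**raw.get("thresholds", {}))
        return cls(simulation=sim, inputs=inputs, thresholds=thresholds,
                   n_ctr=raw.get("n_ctr", 150), n_ctr_con=raw.get("n_ctr_con", 150),
                   seed=raw.get("seed", 0), outdir=raw.get("outdir", "ejcsplice_out"))


def _simconfig_from_dict(d: dict) -> SimConfig:
    for k in ("exons_per_gene", "psi_control_range", "conditions",
              "affected_conditions"):
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return SimConfig(**d)


# ---------------------------------------------------------------------------

def summarize_categories(events) -> pd.DataFrame:
    """Counts and percentages per direction x annotation class; the
    percentages are of the total categorized set (NaN when empty)."""
    rows = []
    total = len(events)
    for direction in ("+", "-"):
        for annot in ("ALT", "CON"):
            n = sum(1 for e in events
                    if e.direction == direction and e.annot_class == annot)
            rows.append(dict(direction=direction, annot_class=annot, count=n))
    df = pd.DataFrame(rows)
    df["percent"] = (100.0 * df["count"] / total) if total else float("nan")
    return df


def _load_or_simulate(config: PipelineConfig, outdir: Path, written: list, log: list):
    if config.simulation is not None:
        sim = config.simulation
        log.append(f"simulation seed = {sim.seed}; n_genes = {sim.n_genes}")
        annotation, genome = generate_annotation(sim)
        sizes = {c: len(s) for c, s in genome.items()}
        events = simulate_event_tables(annotation, sim)
        mrna, clip, _levels = simulate_coverage(annotation, sizes, sim)
        records = simulate_expression_counts(annotation, genome, sim)
        # persist the simulated inputs so the catalog stage runs off files,
        # the same path as for real data
        annotation.to_gtf(_w(outdir / "annotation.gtf", written))
        write_fasta(_w(outdir / "genome.fa", written), genome)
        events.write(outdir)
        for (c, r) in sorted(events.miso):
            written.append(outdir / f"miso_{c}_rep{r}.tsv")
        written += [outdir / "diffsplice.tsv", outdir / "truth.tsv"]
        for strand, tag in (("+", "plus"), ("-", "minus")):
            mrna.to_bedgraph(_w(outdir / f"mrna_{tag}.bedgraph", written), strand)
            clip.to_bedgraph(_w(outdir / f"clip_{tag}.bedgraph", written), strand)
        pd.DataFrame([(r.gene_id, r.condition, r.n_reads, r.transcript_length,
                       r.read_length) for r in records],
                     columns=["gene_id", "condition", "n_reads",
                              "transcript_length", "read_length"]
                     ).to_csv(_w(outdir / "counts.tsv", written), sep="\t", index=False)
        miso_tables = events.miso
        diffsplice_df = events.diffsplice
        contrasts = sim.conditions
        n_reps = sim.n_replicates
    else:
        inp = config.inputs
        for p in [inp.annotation_gtf, inp.genome_fasta, inp.diffsplice_table,
                  inp.counts_tsv, *inp.miso_tables.values(),
                  *inp.clip_bedgraph.values(), *inp.mrna_bedgraph.values()]:
            if p is not None and not Path(p).exists():
                raise PipelineInputError(f"missing input: {p}")
        annotation = GenomeAnnotation.from_gtf(inp.annotation_gtf)
        genome = read_fasta(inp.genome_fasta)
        sizes = {c: len(s) for c, s in genome.items()}
        miso_tables = {}
        for key, path in inp.miso_tables.items():
            contrast, rep = key.rsplit(":", 1)
            miso_tables[(contrast, int(rep))] = pd.read_csv(path, sep="\t")
        diffsplice_df = (pd.read_csv(inp.diffsplice_table, sep="\t")
                         if inp.diffsplice_table else pd.DataFrame(columns=cat.DIFFSPLICE_COLUMNS))
        mrna = CoverageTrack.from_bedgraph(inp.mrna_bedgraph, sizes) \
            if inp.mrna_bedgraph else CoverageTrack(sizes)
        clip = CoverageTrack.from_bedgraph(inp.clip_bedgraph, sizes) \
            if inp.clip_bedgraph else CoverageTrack(sizes)
        records = []
        if inp.counts_tsv:
            df = pd.read_csv(inp.counts_tsv, sep="\t")
            records = [cat.ExpressionRecord(r.gene_id, r.condition, int(r.n_reads),
                                            int(r.transcript_length), int(r.read_length))
                       for r in df.itertuples(index=False)]
        contrasts = tuple(sorted({c for c, _ in miso_tables}))
        n_reps = max((r for _, r in miso_tables), default=0)
    return annotation, genome, miso_tables, diffsplice_df, mrna, clip, records, \
        contrasts, n_reps


def _w(path: Path, written: list) -> Path:
    written.append(path)
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the summary dict (also written as
    JSON). Partial outputs are removed when a stage fails."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, outdir, written)
    except Exception:
        for p in written:
            Path(p).unlink(missing_ok=True)
        raise


def _run(config: PipelineConfig, outdir: Path, written: list) -> dict:
    th = config.thresholds
    log: list[str] = [f"pipeline seed = {config.seed}"]
    (annotation, genome, miso_tables, diffsplice_df, mrna, clip, records,
     contrasts, n_reps) = _load_or_simulate(config, outdir, written, log)

    # ---- expression filter -------------------------------------------------
    expressed = cat.expression_filter(records, threshold=th.coverage)
    log.append(f"expression filter: coverage = read_length*reads/transcript_length "
               f">= {th.coverage} in control and >= 1 KD condition (inclusive); "
               f"{len(expressed)} genes retained")
    fcs = cat.fold_changes(records) if records else {}

    # ---- catalog -----------------------------------------------------------
    miso_th = cat.MisoThresholds(
        delta_psi=th.delta_psi, evidence=th.evidence,
        min_inclusion=th.min_inclusion, min_skipping=th.min_skipping,
        min_total=th.min_total)
    log.append(
        "caller filter (all strict): |dPsi| > %g AND evidence > %g AND "
        "inclusion reads > %d AND skipping reads > %d AND inclusion+skipping > %d"
        % (th.delta_psi, th.evidence, th.min_inclusion, th.min_skipping, th.min_total))
    tmp = outdir / "_parse.tsv"
    all_miso_parsed = []
    per_contrast_reps: dict[str, dict[int, list]] = {}
    for (contrast, rep), df in sorted(miso_tables.items()):
        df.to_csv(tmp, sep="\t", index=False)
        evs = [e for e in cat.parse_event_table(tmp, "miso")
               if isinstance(e, cat.CassetteEvent)]
        all_miso_parsed.extend(evs)
        per_contrast_reps.setdefault(contrast, {})[rep] = cat.filter_miso_events(
            evs, miso_th)
    tmp.unlink(missing_ok=True)
    miso_sig = []
    for contrast in sorted(per_contrast_reps):
        reps = per_contrast_reps[contrast]
        rep_ids = sorted(reps)
        inter = reps[rep_ids[0]]
        for r in rep_ids[1:]:
            inter = cat.intersect_replicates(inter, reps[r])
        miso_sig.extend(inter)
    miso_events = cat.combine_contrasts(miso_sig)
    log.append(f"caller A: {len(miso_events)} events significant in both replicates")

    ds_parsed = []
    if len(diffsplice_df):
        diffsplice_df.to_csv(tmp, sep="\t", index=False)
        ds_parsed = [e for e in cat.parse_event_table(tmp, "diffsplice")
                     if isinstance(e, cat.CassetteEvent)]
        tmp.unlink(missing_ok=True)
    ds_sig = [e for e in ds_parsed
              if all(abs(d) > th.delta_psi for d in e.delta_psi.values())
              and all(v > th.delta_psi for v in e.evidence.values())]
    ds_sig, ds_audit = cat.resolve_diffsplice_events(ds_sig, annotation)
    ds_sig = cat.combine_contrasts(ds_sig)
    log.append(f"caller B: {len(ds_sig)} significant events "
               f"(|dPsi| > {th.delta_psi}, sqrt-JSD > {th.delta_psi}); "
               f"{len(ds_audit)} unresolved")

    merged, merge_audit = cat.merge_catalogs(miso_events, ds_sig)
    categorized, cls_audit = cat.classify_events(
        merged, annotation, delta_threshold=th.delta_psi)
    categorized = [e for e in categorized if e.direction in "+-"]
    log.append(f"merged catalog: {len(merged)} events; categorized "
               f"(direction in at least one EJC contrast, strict |dPsi| > "
               f"{th.delta_psi}): {len(categorized)}")

    ctr, ctr_con = cat.build_controls(
        all_miso_parsed, annotation, expressed,
        config.n_ctr, config.n_ctr_con, seed=config.seed,
        max_delta=th.ctr_max_delta,
        psi_range=(th.ctr_psi_low, th.ctr_psi_high))
    log.append(f"controls: Ctr |dPsi| < {th.ctr_max_delta} in every EJC contrast, "
               f"Psi in ({th.ctr_psi_low};{th.ctr_psi_high}) open -> {len(ctr)}; "
               f"CtrCON constitutive triplets -> {len(ctr_con)}")

    cat.events_to_dataframe(categorized).to_csv(
        _w(outdir / "events_categorized.tsv", written), sep="\t", index=False)
    cat.events_to_dataframe(ctr).to_csv(
        _w(outdir / "controls_ctr.tsv", written), sep="\t", index=False)
    cat.events_to_dataframe(ctr_con).to_csv(
        _w(outdir / "controls_ctr_con.tsv", written), sep="\t", index=False)
    audit_rows = [dict(event_id=e.event_id, reason=r)
                  for e, r in ds_audit + merge_audit + cls_audit]
    pd.DataFrame(audit_rows, columns=["event_id", "reason"]).to_csv(
        _w(outdir / "audit.tsv", written), sep="\t", index=False)

    # ---- features ----------------------------------------------------------
    donor_model, acceptor_model = _train_models(annotation, genome)
    motif_sets = {k: feat.MotifSet.bundled_synthetic(k)
                  for k in ("ESE", "ESS", "ISE", "ISS")}
    groups = {"+": [e for e in categorized if e.direction == "+"],
              "-": [e for e in categorized if e.direction == "-"],
              "Ctr": ctr, "CtrCON": ctr_con}
    feat_df = _feature_table(groups, genome, donor_model, acceptor_model, motif_sets)
    feat_df.to_csv(_w(outdir / "features.tsv", written), sep="\t", index=False)
    tests_df = _group_tests(feat_df)
    tests_df.to_csv(_w(outdir / "group_tests.tsv", written), sep="\t", index=False)
    log.append("group comparisons: two-sided Mann-Whitney-Wilcoxon; "
               "BH-adjusted p reported alongside raw")

    # ---- splicing maps -----------------------------------------------------
    map_groups = {k: v for k, v in groups.items() if v}
    profiles = splicemap.build_map(map_groups, clip, mrna, width=th.window)
    splicemap.profiles_to_dataframe(profiles).to_csv(
        _w(outdir / "splicing_map.tsv", written), sep="\t", index=False)
    intron_profiles = splicemap.build_intron_map(map_groups, clip, mrna, width=th.window)
    splicemap.profiles_to_dataframe(intron_profiles).to_csv(
        _w(outdir / "splicing_map_introns.tsv", written), sep="\t", index=False)
    log.append(f"splicing maps: {th.window} nt from the exon-intron border; "
               "CLIP/mRNA per position, mean over exons, max-scaled per category")

    # ---- NMD / AS-NMD ------------------------------------------------------
    ptc_status, gene_of_event = _ptc_statuses(categorized, annotation, genome)
    flags = nmd.asnmd_candidates(categorized, ptc_status, gene_of_event, fcs,
                                 fc_threshold=th.fold_change)
    flags.to_csv(_w(outdir / "nmd_flags.tsv", written), sep="\t", index=False)
    n_ptc = int(flags["ptc_bearing"].sum())
    n_asnmd = int((flags["status"] == "AS-NMD_candidate").sum())
    log.append(f"PTC rule: stop > 50 nt upstream of the last junction (strict); "
               f"AS-NMD flag: PTC-bearing AND fold change > {th.fold_change} "
               f"(strict) in >= 1 EJC KD; {n_ptc} PTC-bearing, {n_asnmd} candidates")

    # ---- summary -----------------------------------------------------------
    summary_df = summarize_categories(categorized)
    summary_df.to_csv(_w(outdir / "category_counts.tsv", written), sep="\t", index=False)
    n_cat = len(categorized)
    n_up = sum(1 for e in categorized if e.direction == "+")
    summary = {
        "n_merged": len(merged),
        "n_categorized": n_cat,
        "n_skipping_up": n_up,
        "n_inclusion_up": n_cat - n_up,
        "pct_skipping_up": (100.0 * n_up / n_cat) if n_cat else None,
        "n_ctr": len(ctr),
        "n_ctr_con": len(ctr_con),
        "n_expressed_genes": len(expressed),
        "n_ptc_bearing": n_ptc,
        "pct_ptc_bearing": (100.0 * n_ptc / n_cat) if n_cat else None,
        "n_asnmd_candidates": n_asnmd,
        "pct_asnmd_of_ptc": (100.0 * n_asnmd / n_ptc) if n_ptc else None,
        "seed": config.seed,
    }
    (_w(outdir / "summary.json", written)).write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (_w(outdir / "run.log", written)).write_text("\n".join(log) + "\n")
    return summary


def _train_models(annotation: GenomeAnnotation, genome: dict[str, str]):
    """Fit the splice-site models on all junctions in the annotation."""
    donors, acceptors = [], []
    for gene in annotation.genes:
        for i, e in enumerate(gene.exons):
            try:
                if i < len(gene.exons) - 1:
                    donors.append(feat.donor_site_seq(
                        genome, gene.chrom, gene.strand, e.start, e.end))
                if i > 0:
                    acceptors.append(feat.acceptor_site_seq(
                        genome, gene.chrom, gene.strand, e.start, e.end))
            except feat.SequenceError:
                continue
    donors = [s for s in donors if len(s) == feat.DONOR_LENGTH]
    acceptors = [s for s in acceptors if len(s) == feat.ACCEPTOR_LENGTH]
    donor_model = (feat.train_site_model(donors, "donor")
                   if donors else feat.default_donor_model())
    acceptor_model = (feat.train_site_model(acceptors, "acceptor")
                      if acceptors else feat.default_acceptor_model())
    return donor_model, acceptor_model


def _event_seq(genome, chrom, strand, start, end):
    from .annotation import revcomp
    s = genome[chrom][start:end].upper()
    return s if strand == "+" else revcomp(s)


def _feature_table(groups, genome, donor_model, acceptor_model, motif_sets):
    rows = []
    for group in sorted(groups):
        for ev in groups[group]:
            fl = feat.flank_lengths(ev)
            if not fl.valid:
                continue
            row = dict(group=group, event_id=ev.event_id,
                       upstream_intron=fl.upstream_intron,
                       downstream_intron=fl.downstream_intron,
                       upstream_exon=fl.upstream_exon,
                       cassette_exon=fl.cassette_exon,
                       downstream_exon=fl.downstream_exon)
            try:
                row["ca_acceptor_bits"] = acceptor_model.score(feat.acceptor_site_seq(
                    genome, ev.chrom, ev.strand, ev.ca_start, ev.ca_end))
                row["ca_donor_bits"] = donor_model.score(feat.donor_site_seq(
                    genome, ev.chrom, ev.strand, ev.ca_start, ev.ca_end))
            except feat.SequenceError:
                row["ca_acceptor_bits"] = np.nan
                row["ca_donor_bits"] = np.nan
            ca_seq = _event_seq(genome, ev.chrom, ev.strand, ev.ca_start, ev.ca_end)
            for kind in ("ESE", "ESS"):
                row[f"ca_{kind.lower()}_freq"] = feat.sre_frequency(
                    ca_seq, motif_sets[kind])
            if ev.strand == "+":
                up_i = (ev.up_end, ev.ca_start)
                dn_i = (ev.ca_end, ev.dn_start)
            else:
                up_i = (ev.ca_end, ev.up_start)
                dn_i = (ev.dn_end, ev.ca_start)
            for tag, (a, b) in (("up_intron", up_i), ("dn_intron", dn_i)):
                iseq = _event_seq(genome, ev.chrom, ev.strand, a, b)
                for kind in ("ISE", "ISS"):
                    row[f"{tag}_{kind.lower()}_freq"] = feat.sre_frequency(
                        iseq, motif_sets[kind])
            rows.append(row)
    return pd.DataFrame(rows)


FEATURE_COLUMNS = ["upstream_intron", "downstream_intron", "cassette_exon",
                   "ca_acceptor_bits", "ca_donor_bits", "ca_ese_freq",
                   "ca_ess_freq", "up_intron_ise_freq", "up_intron_iss_freq",
                   "dn_intron_ise_freq", "dn_intron_iss_freq"]


def _group_tests(feat_df: pd.DataFrame) -> pd.DataFrame:
    pairs = [("+", "Ctr"), ("-", "Ctr"), ("+", "-")]
    rows = []
    for col in FEATURE_COLUMNS:
        if col not in feat_df.columns:
            continue
        for a, b in pairs:
            va = feat_df.loc[feat_df["group"] == a, col].dropna()
            vb = feat_df.loc[feat_df["group"] == b, col].dropna()
            if len(va) == 0 or len(vb) == 0:
                continue
            u, p = feat.compare_groups(va, vb)
            rows.append(dict(feature=col, group_a=a, group_b=b,
                             n_a=len(va), n_b=len(vb), U=u, p_raw=p))
    df = pd.DataFrame(rows, columns=["feature", "group_a", "group_b",
                                     "n_a", "n_b", "U", "p_raw"])
    if len(df):
        df["p_bh"] = false_discovery_control(df["p_raw"], method="bh")
    else:
        df["p_bh"] = []
    return df


def _ptc_statuses(events, annotation: GenomeAnnotation, genome):
    ptc_status: dict[str, tuple[bool, bool]] = {}
    gene_of_event: dict[str, str] = {}
    for ev in events:
        hit = annotation.lookup_exon(ev.chrom, ev.strand, ev.ca_start, ev.ca_end)
        if hit is None:
            continue
        gene, idx = hit
        gene_of_event[ev.event_id] = gene.gene_id
        full = gene.transcripts[0]
        inc = nmd.isoform_orf(gene, full, genome)
        skp = nmd.isoform_orf(gene, nmd.skipping_isoform(gene, idx), genome)
        inc_ptc = bool(inc and nmd.find_ptc(inc).is_ptc)
        skp_ptc = bool(skp and nmd.find_ptc(skp).is_ptc)
        ptc_status[ev.event_id] = (inc_ptc, skp_ptc)
    return ptc_status, gene_of_event
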