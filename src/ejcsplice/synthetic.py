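"""Synthetic data with known ground truth for the whole pipeline.

Generates multi-exon gene models with cassette exons, a genome sequence
with embedded donor/acceptor splice-site contexts, binomially sampled
inclusion/skipping read counts at set true Psi per condition (the two
caller dialects), strand-aware mRNA and CLIP coverage with a binding
peak at a fixed offset from 3' exon ends (canonical EJC position,
-24 nt), per-gene read counts, and optional planted regulatory motifs.

All randomness flows from ``SimConfig.seed`` through independent
deterministic streams, so a fixed seed gives byte-identical output
files.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import Exon, Gene, GenomeAnnotation, Transcript, revcomp, scan_orf
from .catalog import (ALL_CONTRASTS, DIFFSPLICE_COLUMNS, EJC_CONTRASTS,
                      MISO_COLUMNS, ExpressionRecord)
from .features import (BASES, MotifSet, default_acceptor_model,
                       default_donor_model)
from .tracks import CoverageTrack


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Lengths are in nucleotides; Psi values in [0,1]. ``true_psi``, when
    given, fixes the per-condition inclusion level of affected events
    explicitly (must contain the key 'control' and every condition);
    otherwise the control Psi is drawn uniformly from
    ``psi_control_range`` and knockdown Psi offset by ``delta_psi`` in
    the EJC contrasts.
    """

    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (5, 9)
    exon_length_log_mean: float = math.log(120.0)
    exon_length_log_sd: float = 0.35
    intron_length_log_mean: float = math.log(665.0)
    intron_length_log_sd: float = 0.8
    min_exon_length: int = 30
    min_intron_length: int = 80
    cassette_fraction: float = 0.3
    #: fraction of cassette exons whose length is not a multiple of 3, so
    #: skipping shifts the reading frame (the AS-NMD-prone events)
    frameshift_fraction: float = 0.35
    con_event_fraction: float = 0.08
    affected_fraction: float = 0.3
    skip_up_share: float = 0.65
    delta_psi: float = 0.3
    psi_control_range: tuple[float, float] = (0.35, 0.65)
    true_psi: dict[str, float] | None = None
    conditions: tuple[str, ...] = ALL_CONTRASTS
    affected_conditions: tuple[str, ...] = EJC_CONTRASTS
    n_replicates: int = 2
    read_depth: float = 100.0
    read_length: int = 51
    mrna_mean_coverage: float = 30.0
    expression_log_sd: float = 0.5
    clip_peak_offset: int = -24
    clip_peak_height: float = 20.0
    clip_background: float = 2.0
    clip_peak_sd: float = 2.0
    motif_plant_density: float = 0.0
    overdispersion: float = 0.0
    asnmd_fraction: float = 0.5
    asnmd_fold_change: float = 2.0
    intergenic_gap: int = 2000
    genes_per_chrom: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SimulationError("n_genes must be >= 1")
        if self.exons_per_gene[0] < 3:
            raise SimulationError("genes need >= 3 exons for cassette events")
        for name in ("exon_length_log_sd", "intron_length_log_sd",
                     "expression_log_sd", "clip_peak_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.min_exon_length < 1 or self.min_intron_length < 35:
            # introns must hold a 6-nt donor context and a 20-nt acceptor tract
            raise SimulationError("minimum lengths too small for splice-site contexts")
        for name in ("cassette_fraction", "frameshift_fraction",
                     "con_event_fraction", "affected_fraction",
                     "skip_up_share", "asnmd_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0,1]")
        lo, hi = self.psi_control_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise SimulationError("psi_control_range must be within [0,1]")
        if self.true_psi is not None:
            needed = {"control", *self.conditions}
            missing = needed - set(self.true_psi)
            if missing:
                raise SimulationError(f"true_psi missing conditions {sorted(missing)}")
            if any(not 0.0 <= p <= 1.0 for p in self.true_psi.values()):
                raise SimulationError("true_psi values must be in [0,1]")
        if self.motif_plant_density < 0:
            raise SimulationError("motif_plant_density must be >= 0")
        if self.clip_background < 0 or self.clip_peak_height < 0:
            raise SimulationError("CLIP coverage parameters must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("exons_per_gene", "psi_control_range", "conditions",
                  "affected_conditions"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)


def _stream(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


def _codes_to_str(codes: np.ndarray) -> str:
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return lut[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# Annotation + genome
# ---------------------------------------------------------------------------

def generate_annotation(config: SimConfig) -> tuple[GenomeAnnotation, dict[str, str]]:
    """Build gene models and the genome sequence they live on.

    Every gene has >= 3 exons; internal exons are flagged alternative
    with probability ``cassette_fraction``; donor (9-mer) and acceptor
    (23-mer) contexts are sampled from the canonical position models and
    embedded at every junction; each alternative exon additionally gets a
    skipping transcript.
    """
    config.validate()
    rng = _stream(config, 0)
    donor = default_donor_model()
    acceptor = default_acceptor_model()
    genes: list[Gene] = []
    genome: dict[str, str] = {}
    chrom_parts: list[str] = []
    cursor = 0
    chrom_i = 1

    def flush_chrom():
        nonlocal chrom_parts, cursor, chrom_i
        if chrom_parts:
            genome[f"chr{chrom_i}"] = "".join(chrom_parts)
            chrom_parts = []
            cursor = 0
            chrom_i += 1

    for gi in range(config.n_genes):
        if gi > 0 and gi % config.genes_per_chrom == 0:
            flush_chrom()
        chrom = f"chr{chrom_i}"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = np.maximum(
            config.min_exon_length,
            np.round(rng.lognormal(config.exon_length_log_mean,
                                   config.exon_length_log_sd, n_ex)).astype(int))
        intron_lens = np.maximum(
            config.min_intron_length,
            np.round(rng.lognormal(config.intron_length_log_mean,
                                   config.intron_length_log_sd, n_ex - 1)).astype(int))
        alt_flags = np.zeros(n_ex, dtype=bool)
        alt_flags[1:-1] = rng.random(n_ex - 2) < config.cassette_fraction
        # control the reading-frame consequence of skipping: most cassette
        # exons keep the frame (length % 3 == 0), a set fraction shift it
        for i in np.flatnonzero(alt_flags):
            rem = int(exon_lens[i]) % 3
            if rng.random() < config.frameshift_fraction:
                if rem == 0:
                    exon_lens[i] += int(rng.integers(1, 3))
            elif rem != 0:
                exon_lens[i] += 3 - rem
        strand = "+" if rng.random() < 0.5 else "-"

        # region in transcript orientation
        L = int(exon_lens.sum() + intron_lens.sum())
        region = _random_bases(rng, L)
        exon_spans = []
        pos = 0
        for i in range(n_ex):
            exon_spans.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_ex - 1:
                pos += int(intron_lens[i])
        for i in range(n_ex - 1):
            e_end = exon_spans[i][1]
            n_start = exon_spans[i + 1][0]
            dsite = np.frombuffer(donor.sample(1, rng)[0].encode(), dtype=np.uint8)
            asite = np.frombuffer(acceptor.sample(1, rng)[0].encode(), dtype=np.uint8)
            region[e_end - 3:e_end + 6] = _encode_bytes(dsite)
            region[n_start - 20:n_start + 3] = _encode_bytes(asite)

        # ORF anchors: ATG near the transcript start, an in-frame stop in
        # the last exon (earlier chance stops are legitimate and found by
        # scanning)
        t_len = int(exon_lens.sum())
        t_to_region = _transcript_to_region_map(exon_spans)
        _plant(region, t_to_region, 9, "ATG")
        last_exon_t_start = t_len - int(exon_lens[-1])
        stop_t = 9 + 3 * ((t_len - 6 - 9) // 3)
        if stop_t < last_exon_t_start + 3:
            stop_t = 9 + 3 * -(-(last_exon_t_start + 3 - 9) // 3)
        _plant(region, t_to_region, stop_t, "TAA")
        # keep the inclusion-isoform reading frame open up to the planted
        # stop: recode chance in-frame stop codons (third base -> C)
        for tpos in range(12, stop_t, 3):
            codon = "".join("ACGT"[region[t_to_region(tpos + k)]] for k in range(3))
            if codon in ("TAA", "TAG", "TGA"):
                region[t_to_region(tpos + 2)] = "ACGT".index("C")

        gap = _random_bases(rng, config.intergenic_gap)
        chrom_parts.append(_codes_to_str(gap))
        cursor += config.intergenic_gap
        gene_start = cursor
        region_str = _codes_to_str(region)
        chrom_parts.append(region_str if strand == "+" else revcomp(region_str))
        cursor += L

        exons = []
        for (a, b), alt in zip(exon_spans, alt_flags):
            if strand == "+":
                exons.append(Exon(gene_start + a, gene_start + b, bool(alt)))
            else:
                exons.append(Exon(gene_start + L - b, gene_start + L - a, bool(alt)))
        gene = Gene(f"g{gi + 1:04d}", chrom, strand, exons)
        full = Transcript(f"{gene.gene_id}.t1", tuple(range(n_ex)), cds_start=9)
        gene.transcripts.append(full)
        ti = 2
        for i in np.flatnonzero(alt_flags):
            skip = Transcript(f"{gene.gene_id}.t{ti}",
                              tuple(j for j in range(n_ex) if j != i), cds_start=9)
            gene.transcripts.append(skip)
            ti += 1
        genes.append(gene)
    flush_chrom()

    annotation = GenomeAnnotation(genes)
    for gene in annotation.genes:
        for t in gene.transcripts:
            seq = gene.transcript_seq(t, genome)
            t.cds_end = scan_orf(seq, t.cds_start)
    return annotation, genome


def _encode_bytes(site: np.ndarray) -> np.ndarray:
    out = np.zeros(len(site), dtype=np.int8)
    for b, i in zip(b"ACGT", range(4)):
        out[site == b] = i
    return out


def _transcript_to_region_map(exon_spans):
    def f(tpos: int) -> int:
        off = 0
        for a, b in exon_spans:
            if tpos < off + (b - a):
                return a + (tpos - off)
            off += b - a
        raise SimulationError("transcript position outside exons")
    return f


def _plant(region: np.ndarray, t_to_region, tpos: int, word: str) -> None:
    for k, ch in enumerate(word):
        region[t_to_region(tpos + k)] = "ACGT".index(ch)


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

@dataclass
class SimulatedEvents:
    #: {(contrast, replicate): DataFrame} in the miso dialect
    miso: dict[tuple[str, int], pd.DataFrame]
    #: replicate-aware caller table (diffsplice dialect)
    diffsplice: pd.DataFrame
    #: per-event ground truth (true Psi per condition, direction)
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (contrast, rep), df in sorted(self.miso.items()):
            df.to_csv(outdir / f"miso_{contrast}_rep{rep}.tsv", sep="\t", index=False)
        self.diffsplice.to_csv(outdir / "diffsplice.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _draw_inclusion(rng, n, psi, overdispersion):
    if overdispersion > 0:
        rho = overdispersion
        a = max(psi, 1e-9) * (1.0 / rho - 1.0)
        b = max(1.0 - psi, 1e-9) * (1.0 / rho - 1.0)
        p = rng.beta(a, b)
    else:
        p = psi
    return int(rng.binomial(n, p))


def _bernoulli_jsd(p: float, q: float) -> float:
    def xlog(x, y):
        return 0.0 if x == 0 else x * math.log2(x / y)

    m0, m1 = ((1 - p) + (1 - q)) / 2, (p + q) / 2
    kl_p = xlog(p, m1) + xlog(1 - p, m0)
    kl_q = xlog(q, m1) + xlog(1 - q, m0)
    return 0.5 * kl_p + 0.5 * kl_q


def simulate_event_tables(annotation: GenomeAnnotation,
                          config: SimConfig) -> SimulatedEvents:
    """Sample observed event tables from the true inclusion levels.

    Per contrast and replicate, informative read totals are Poisson at
    the configured depth and inclusion reads binomial at the true Psi;
    the observed Psi-hat is inc/(inc+skip). The evidence score standing
    in for the caller's Bayes factor is 2*|dPsi-hat|*sqrt(total reads),
    monotone in both effect size and depth. The replicate-aware table is
    built from reads pooled over replicates, with a Jensen-Shannon
    divergence score.
    """
    config.validate()
    rng = _stream(config, 1)
    events = []  # (gene, exon_idx, planted_con)
    for gene in annotation.genes:
        alt_idx = [i for i, e in enumerate(gene.exons) if e.alternative]
        for i in alt_idx:
            events.append((gene, i, False))
        internal_con = [i for i in range(1, len(gene.exons) - 1)
                        if not gene.exons[i].alternative]
        if internal_con and rng.random() < config.con_event_fraction:
            events.append((gene, int(rng.choice(internal_con)), True))

    truth_rows = []
    miso_rows: dict[tuple[str, int], list] = {
        (c, r): [] for c in config.conditions
        for r in range(1, config.n_replicates + 1)}
    ds_rows = []
    for gene, idx, planted_con in events:
        ca = gene.exons[idx]
        up = gene.exons[idx - 1]
        dn = gene.exons[idx + 1]
        event_id = f"{gene.chrom}:{ca.start}-{ca.end}:{gene.strand}"
        if config.true_psi is not None:
            psi_c = config.true_psi["control"]
        else:
            psi_c = float(rng.uniform(*config.psi_control_range))
        affected = planted_con or (rng.random() < config.affected_fraction)
        if planted_con:
            direction = "+"
        else:
            direction = "+" if rng.random() < config.skip_up_share else "-"
        psi_kd = {}
        for cond in config.conditions:
            if config.true_psi is not None:
                psi_kd[cond] = (config.true_psi[cond]
                                if affected and cond in config.affected_conditions
                                else psi_c)
            elif affected and cond in config.affected_conditions:
                shift = -config.delta_psi if direction == "+" else config.delta_psi
                psi_kd[cond] = float(np.clip(psi_c + shift, 0.0, 1.0))
            else:
                psi_kd[cond] = psi_c
        truth_rows.append(dict(
            event_id=event_id, gene_id=gene.gene_id, chrom=gene.chrom,
            strand=gene.strand, ca_start=ca.start, ca_end=ca.end,
            planted_con=planted_con, affected=affected,
            direction=direction if affected else "none",
            psi_control=psi_c,
            **{f"psi_{c}": psi_kd[c] for c in config.conditions}))

        # exon-centric caller: annotated alternative events only
        pooled = {c: [0, 0, 0, 0] for c in config.conditions}  # inc_c, n_c, inc_k, n_k
        for rep in range(1, config.n_replicates + 1):
            n_c = max(1, int(rng.poisson(config.read_depth)))
            inc_c = _draw_inclusion(rng, n_c, psi_c, config.overdispersion)
            for cond in config.conditions:
                n_k = max(1, int(rng.poisson(config.read_depth)))
                inc_k = _draw_inclusion(rng, n_k, psi_kd[cond], config.overdispersion)
                pooled[cond][0] += inc_c
                pooled[cond][1] += n_c
                pooled[cond][2] += inc_k
                pooled[cond][3] += n_k
                if planted_con:
                    continue
                p1 = inc_c / n_c
                p2 = inc_k / n_k
                bf = 2.0 * abs(p1 - p2) * math.sqrt(n_c + n_k)
                miso_rows[(cond, rep)].append(dict(
                    event_id=event_id, event_type="SE",
                    chrom=gene.chrom, strand=gene.strand,
                    up_start=up.start, up_end=up.end,
                    ca_start=ca.start, ca_end=ca.end,
                    dn_start=dn.start, dn_end=dn.end,
                    contrast=cond, psi1=p1, psi2=p2, diff=p1 - p2,
                    bayes_factor=bf,
                    inc_reads=inc_c + inc_k,
                    skip_reads=(n_c - inc_c) + (n_k - inc_k)))
        # replicate-aware caller: flank boundaries only
        if gene.strand == "+":
            up_end, dn_start = up.end, dn.start
        else:
            up_end, dn_start = dn.end, up.start
        for cond in config.conditions:
            inc_c, n_c, inc_k, n_k = pooled[cond]
            p1, p2 = inc_c / n_c, inc_k / n_k
            ds_rows.append(dict(
                asm_id=f"asm_{event_id}", event_type="SE",
                chrom=gene.chrom, strand=gene.strand,
                up_exon_end=up_end, dn_exon_start=dn_start,
                contrast=cond, psi1=p1, psi2=p2, diff=p1 - p2,
                sqrt_jsd=math.sqrt(_bernoulli_jsd(p1, p2))))

    miso = {k: pd.DataFrame(v, columns=MISO_COLUMNS) for k, v in miso_rows.items()}
    diffsplice = pd.DataFrame(ds_rows, columns=DIFFSPLICE_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return SimulatedEvents(miso=miso, diffsplice=diffsplice, truth=truth)


# ---------------------------------------------------------------------------
# Coverage and counts
# ---------------------------------------------------------------------------

def simulate_coverage(annotation: GenomeAnnotation, chrom_sizes: dict[str, int],
                      config: SimConfig
                      ) -> tuple[CoverageTrack, CoverageTrack, dict[str, float]]:
    """mRNA and CLIP coverage tracks plus the per-gene expression levels.

    mRNA coverage is uniform per exon at the gene's expression level with
    Poisson noise. CLIP coverage is background plus a Gaussian-shaped
    peak of the configured height centred ``clip_peak_offset`` nt from
    each exon's 3' border (transcript orientation), scaled by the gene's
    relative expression, with Poisson noise. Peaks that fall outside
    short exons are truncated with a warning.
    """
    config.validate()
    rng = _stream(config, 2)
    mrna = CoverageTrack(chrom_sizes)
    clip = CoverageTrack(chrom_sizes)
    levels: dict[str, float] = {}
    truncated = 0
    for gene in annotation.genes:
        level = float(rng.lognormal(math.log(config.mrna_mean_coverage),
                                    config.expression_log_sd))
        levels[gene.gene_id] = level
        scale = level / config.mrna_mean_coverage
        for e in gene.exons:
            mrna.add(gene.chrom, gene.strand, e.start,
                     rng.poisson(level, e.length).astype(float))
            rel = np.arange(e.length)
            r0 = e.length + config.clip_peak_offset
            if r0 < 0:
                truncated += 1
            mean = config.clip_background + config.clip_peak_height * np.exp(
                -0.5 * ((rel - r0) / max(config.clip_peak_sd, 1e-9)) ** 2)
            vals = rng.poisson(scale * mean).astype(float)
            if gene.strand == "-":
                vals = vals[::-1]
            clip.add(gene.chrom, gene.strand, e.start, vals)
    if truncated:
        warnings.warn(f"CLIP peak offset beyond exon length for {truncated} exons; "
                      "peaks truncated", stacklevel=2)
    return mrna, clip, levels


def simulate_expression_counts(annotation: GenomeAnnotation, genome: dict[str, str],
                               config: SimConfig) -> list[ExpressionRecord]:
    """Per-gene read counts for each condition.

    Counts are Poisson at coverage * length / read_length. Genes whose
    skipping isoform carries a premature stop (by the 50-nt rule) are
    up-regulated ``asnmd_fold_change``-fold in the EJC knockdowns with
    probability ``asnmd_fraction``, emulating stabilised AS-NMD targets.
    """
    from .nmd import isoform_orf, find_ptc

    config.validate()
    rng = _stream(config, 3)
    records: list[ExpressionRecord] = []
    for gene in annotation.genes:
        full = gene.transcripts[0]
        t_len = gene.transcript_length(full)
        level = float(rng.lognormal(math.log(config.mrna_mean_coverage),
                                    config.expression_log_sd))
        ptc_skip = False
        for t in gene.transcripts[1:]:
            orf = isoform_orf(gene, t, genome)
            if orf is not None and find_ptc(orf).is_ptc:
                ptc_skip = True
                break
        boosted = ptc_skip and rng.random() < config.asnmd_fraction
        for cond in ("control",) + tuple(config.conditions):
            lam = level * t_len / config.read_length
            if boosted and cond in config.affected_conditions:
                lam *= config.asnmd_fold_change
            records.append(ExpressionRecord(
                gene_id=gene.gene_id, condition=cond,
                n_reads=int(rng.poisson(lam)),
                transcript_length=t_len, read_length=config.read_length))
    return records


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

def plant_motifs(sequence: str, motifs: MotifSet, density: float,
                 seed: int | None = None,
                 rng: np.random.Generator | None = None) -> str:
    """Overwrite random non-overlapping positions with motifs from the
    set, at an expected rate of ``density`` occurrences per nucleotide;
    sequence length is preserved."""
    if density < 0:
        raise SimulationError("density must be >= 0")
    if motifs.k > len(sequence):
        raise SimulationError("motif longer than sequence")
    if density == 0 or len(motifs) == 0:
        return sequence
    if rng is None:
        rng = np.random.default_rng(seed)
    n_target = int(rng.poisson(density * len(sequence)))
    seq = list(sequence)
    occupied: list[tuple[int, int]] = []
    planted = 0
    attempts = 0
    while planted < n_target and attempts < 50 * max(n_target, 1):
        attempts += 1
        pos = int(rng.integers(0, len(sequence) - motifs.k + 1))
        if any(pos < e and pos + motifs.k > s for s, e in occupied):
            continue
        motif = motifs.motifs[int(rng.integers(len(motifs)))]
        seq[pos:pos + motifs.k] = list(motif)
        occupied.append((pos, pos + motifs.k))
        planted += 1
    return "".join(seq)
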