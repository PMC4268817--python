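"""Gene models and genome annotation containers.

Coordinates are 0-based, half-open on the forward genomic strand
everywhere inside the package; GTF is emitted and parsed as 1-based
inclusive. Exons of a gene are stored in transcript (5'->3') order, so
on the minus strand genomic starts decrease along the exon list.
"""
from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for inconsistent gene structures or malformed annotation files."""


@dataclass(frozen=True)
class Exon:
    """Genomic exon span; ``alternative`` marks annotated cassette exons."""

    start: int
    end: int
    alternative: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(f"empty exon [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    transcript_id: str
    #: indices into Gene.exons, in transcript order
    exon_indices: tuple[int, ...]
    #: transcript coordinate (0-based) of the first CDS nucleotide
    cds_start: int | None = None
    #: transcript coordinate one past the last nucleotide of the stop codon
    cds_end: int | None = None


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon]  # transcript order
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        starts = [e.start for e in self.exons]
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise AnnotationError(f"{self.gene_id}: overlapping exons")
        expected = starts if self.strand == "+" else starts[::-1]
        if expected != sorted(starts):
            raise AnnotationError(f"{self.gene_id}: exons not in transcript order")

    # ---- structure helpers -------------------------------------------------

    def introns(self) -> list[tuple[int, int]]:
        """Genomic (start, end) of introns between consecutive exons, transcript order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((a.end, b.start))
            else:
                out.append((b.end, a.start))
        return out

    def exon_span(self) -> tuple[int, int]:
        return (min(e.start for e in self.exons), max(e.end for e in self.exons))

    def transcript_exons(self, t: Transcript) -> list[Exon]:
        return [self.exons[i] for i in t.exon_indices]

    def transcript_length(self, t: Transcript) -> int:
        return sum(e.length for e in self.transcript_exons(t))

    def junctions(self, t: Transcript) -> list[int]:
        """1-based transcript coordinates of the last nucleotide of each
        exon except the final one (= exon-exon junction positions)."""
        pos, out = 0, []
        exons = self.transcript_exons(t)
        for e in exons[:-1]:
            pos += e.length
            out.append(pos)
        return out

    def transcript_seq(self, t: Transcript, genome: dict[str, str]) -> str:
        chrom = genome[self.chrom]
        parts = []
        for e in self.transcript_exons(t):
            s = chrom[e.start:e.end]
            parts.append(s if self.strand == "+" else revcomp(s))
        return "".join(parts)


class GenomeAnnotation:
    """A set of gene models with exon-level lookup.

    Invariants: exons within a transcript are non-overlapping and ordered;
    the alternative/constitutive flag of an exon is a property of the gene
    (consistent across its transcripts).
    """

    def __init__(self, genes: list[Gene]):
        self.genes = list(genes)
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise AnnotationError("duplicate gene ids")
        self._exon_index: dict[tuple[str, str, int, int], tuple[str, int]] = {}
        for g in self.genes:
            for i, e in enumerate(g.exons):
                self._exon_index[(g.chrom, g.strand, e.start, e.end)] = (g.gene_id, i)

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def lookup_exon(self, chrom: str, strand: str, start: int, end: int):
        """Return (gene, exon index in transcript order) or None."""
        hit = self._exon_index.get((chrom, strand, start, end))
        if hit is None:
            return None
        gid, idx = hit
        return self._by_id[gid], idx

    def is_alternative(self, chrom: str, strand: str, start: int, end: int) -> bool | None:
        hit = self.lookup_exon(chrom, strand, start, end)
        if hit is None:
            return None
        gene, idx = hit
        return gene.exons[idx].alternative

    def find_exon_between(self, chrom: str, strand: str, up_end: int, dn_start: int):
        """Resolve a cassette exon lying strictly between two flank boundaries.

        ``up_end``/``dn_start`` delimit the genomic gap (as reported by
        splice-graph callers that only emit flank coordinates). Returns
        (gene, exon index) of the unique exon inside the gap, or None.
        """
        lo, hi = min(up_end, dn_start), max(up_end, dn_start)
        hits = []
        for gene in self.genes:
            if gene.chrom != chrom or gene.strand != strand:
                continue
            span = gene.exon_span()
            if span[1] < lo or span[0] > hi:
                continue
            for i, e in enumerate(gene.exons):
                if lo <= e.start and e.end <= hi:
                    hits.append((gene, i))
        if len(hits) == 1:
            return hits[0]
        return None

    def constitutive_triplets(self) -> list[tuple[Gene, tuple[int, int, int]]]:
        """All runs of three successive constitutive exons, excluding the
        first and last exon of the transcript; at most one triplet per gene
        (the first eligible one in transcript order)."""
        out = []
        for gene in self.genes:
            n = len(gene.exons)
            for i in range(1, n - 3):
                trio = gene.exons[i:i + 3]
                if not any(e.alternative for e in trio):
                    out.append((gene, (i, i + 1, i + 2)))
                    break
        return out

    # ---- GTF ---------------------------------------------------------------

    def to_gtf(self, path: str | Path) -> None:
        lines = []
        for g in self.genes:
            span = g.exon_span()
            attrs = f'gene_id "{g.gene_id}";'
            lines.append(_gtf_line(g.chrom, "gene", span[0], span[1], g.strand, attrs))
            for t in g.transcripts:
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                exons = g.transcript_exons(t)
                tspan = (min(e.start for e in exons), max(e.end for e in exons))
                lines.append(_gtf_line(g.chrom, "transcript", tspan[0], tspan[1], g.strand, tattrs))
                for e in exons:
                    cls = "alternative" if e.alternative else "constitutive"
                    lines.append(_gtf_line(
                        g.chrom, "exon", e.start, e.end, g.strand,
                        tattrs + f' exon_class "{cls}";'))
                if t.cds_start is not None and t.cds_end is not None:
                    for (cs, ce) in _transcript_to_genomic(g, t, t.cds_start, t.cds_end):
                        lines.append(_gtf_line(g.chrom, "CDS", cs, ce, g.strand, tattrs))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gtf(cls, path: str | Path) -> "GenomeAnnotation":
        db = gffutils.create_db(
            str(path), ":memory:", keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True)
        genes: list[Gene] = []
        for gf in db.features_of_type("gene"):
            gene_id = gf.attributes["gene_id"][0]
            strand = gf.strand
            exon_coords: dict[tuple[int, int], bool] = {}
            transcripts_raw = []
            for tf in db.children(gf, featuretype="transcript"):
                tid = tf.attributes["transcript_id"][0]
                exons = sorted(
                    db.children(tf, featuretype="exon"), key=lambda e: e.start)
                if strand == "-":
                    exons = exons[::-1]
                coords = []
                for ef in exons:
                    key = (ef.start - 1, ef.end)
                    cls_attr = ef.attributes.get("exon_class", [None])[0]
                    alt = cls_attr == "alternative"
                    exon_coords[key] = exon_coords.get(key, False) or alt
                    coords.append(key)
                cds = sorted(db.children(tf, featuretype="CDS"), key=lambda c: c.start)
                transcripts_raw.append((tid, coords, cds))
            # when no exon_class attributes are present, infer: an exon is
            # alternative if it is absent from at least one transcript
            if not any(exon_coords.values()) and len(transcripts_raw) > 1:
                for key in exon_coords:
                    in_all = all(key in c for _, c, _ in transcripts_raw)
                    exon_coords[key] = not in_all
            ordered = sorted(exon_coords, key=lambda k: k[0])
            if strand == "-":
                ordered = ordered[::-1]
            exon_list = [Exon(s, e, exon_coords[(s, e)]) for s, e in ordered]
            index_of = {k: i for i, k in enumerate(ordered)}
            gene = Gene(gene_id, gf.seqid, strand, exon_list)
            for tid, coords, cds in transcripts_raw:
                t = Transcript(tid, tuple(index_of[c] for c in coords))
                if cds:
                    g_start = cds[0].start - 1
                    g_end = cds[-1].end
                    first = g_start if strand == "+" else g_end - 1
                    last = g_end - 1 if strand == "+" else g_start
                    t.cds_start = _genomic_to_transcript(gene, t, first)
                    t.cds_end = _genomic_to_transcript(gene, t, last) + 1
                gene.transcripts.append(t)
            genes.append(gene)
        return cls(genes)


def _gtf_line(chrom: str, feature: str, start: int, end: int, strand: str, attrs: str) -> str:
    # internal half-open -> GTF 1-based inclusive
    return "\t".join([chrom, "ejcsplice", feature, str(start + 1), str(end),
                      ".", strand, ".", attrs])


def _genomic_to_transcript(gene: Gene, t: Transcript, gpos: int) -> int:
    """0-based transcript coordinate of a genomic position (must be exonic)."""
    off = 0
    for e in gene.transcript_exons(t):
        if e.start <= gpos < e.end:
            within = gpos - e.start if gene.strand == "+" else e.end - 1 - gpos
            return off + within
        off += e.length
    raise AnnotationError(f"position {gpos} not exonic in {t.transcript_id}")


def _transcript_to_genomic(gene: Gene, t: Transcript, tstart: int, tend: int):
    """Genomic half-open spans covering transcript interval [tstart, tend)."""
    spans = []
    off = 0
    for e in gene.transcript_exons(t):
        lo = max(tstart, off)
        hi = min(tend, off + e.length)
        if lo < hi:
            if gene.strand == "+":
                spans.append((e.start + (lo - off), e.start + (hi - off)))
            else:
                spans.append((e.end - (hi - off), e.end - (lo - off)))
        off += e.length
    return sorted(spans)


# ---- FASTA ----------------------------------------------------------------

def write_fasta(path: str | Path, seqs: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            fh.write(textwrap.fill(seqs[name], width) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def scan_orf(seq: str, cds_start: int) -> int | None:
    """Transcript coordinate one past the first in-frame stop codon at or
    after ``cds_start``; None when no stop is reached."""
    for i in range(cds_start, len(seq) - 2, 3):
        if seq[i:i + 3] in STOP_CODONS:
            return i + 3
    return None
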