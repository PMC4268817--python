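"""Premature-termination-codon classification (50-nt rule) and AS-NMD
candidate flagging.

A stop codon is premature when it lies strictly more than 50 nt
upstream of the last exon-exon junction of the spliced transcript
(where the downstream exon junction complex would sit); such isoforms
are NMD substrates. Events producing a PTC+ isoform whose total mRNA
rises more than 1.5-fold in an EJC knockdown are flagged as likely
AS-NMD targets.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation import Gene, Transcript, scan_orf

PTC_DISTANCE_NT = 50


class NmdError(ValueError):
    pass


@dataclass(frozen=True)
class IsoformOrf:
    """Spliced-transcript view of an isoform's reading frame.

    Positions are 1-based transcript coordinates; ``junctions`` holds the
    coordinate of the last nucleotide of every exon but the final one,
    ``stop_codon_end`` the last nucleotide of the stop codon.
    """

    transcript_id: str
    transcript_length: int
    junctions: tuple[int, ...]
    stop_codon_end: int

    def __post_init__(self) -> None:
        if list(self.junctions) != sorted(set(self.junctions)):
            raise NmdError(f"{self.transcript_id}: junctions must be strictly increasing")
        if not 1 <= self.stop_codon_end <= self.transcript_length:
            raise NmdError(f"{self.transcript_id}: stop codon outside transcript")


@dataclass(frozen=True)
class PtcCall:
    is_ptc: bool
    #: signed distance (nt) from the stop codon to the last junction;
    #: positive when the stop is upstream of the junction; None for
    #: junction-less (single-exon) transcripts
    distance_to_last_junction: int | None


def find_ptc(isoform: IsoformOrf) -> PtcCall:
    """Apply the 50-nt rule: premature iff the stop codon lies strictly
    more than 50 nt upstream of the last exon-exon junction. Single-exon
    transcripts are never PTC+ (no junction downstream)."""
    if not isoform.junctions:
        return PtcCall(False, None)
    dist = max(isoform.junctions) - isoform.stop_codon_end
    return PtcCall(dist > PTC_DISTANCE_NT, dist)


def isoform_orf(gene: Gene, t: Transcript, genome: dict[str, str]) -> IsoformOrf | None:
    """Scan an isoform's transcript sequence for its first in-frame stop
    and package the junction layout; None when no stop is reached (no
    annotated ORF or read-through past the 3' end)."""
    if t.cds_start is None:
        return None
    seq = gene.transcript_seq(t, genome)
    stop_end = scan_orf(seq, t.cds_start)
    if stop_end is None:
        return None
    return IsoformOrf(
        transcript_id=t.transcript_id,
        transcript_length=len(seq),
        junctions=tuple(gene.junctions(t)),
        stop_codon_end=stop_end,
    )


def skipping_isoform(gene: Gene, exon_index: int) -> Transcript:
    """Derive the skipping isoform of a cassette event from the inclusion
    transcript (all exons) by dropping the cassette exon; the reading
    frame is re-scanned from the same CDS start."""
    full = gene.transcripts[0]
    if exon_index not in full.exon_indices:
        raise NmdError(f"exon {exon_index} not in inclusion transcript")
    kept = tuple(i for i in full.exon_indices if i != exon_index)
    return Transcript(f"{gene.gene_id}.skip{exon_index}", kept,
                      cds_start=full.cds_start)


def asnmd_candidates(events, ptc_status: dict[str, tuple[bool, bool]],
                     gene_of_event: dict[str, str],
                     fold_changes: dict[str, dict[str, float]],
                     ejc_contrasts=("eIF4A3", "Y14", "MLN51"),
                     fc_threshold: float = 1.5) -> pd.DataFrame:
    """Flag events whose isoforms carry a PTC and whose gene-level mRNA
    rises above ``fc_threshold`` (strict) in at least one EJC knockdown.

    ``ptc_status`` maps event id to (inclusion PTC+, skipping PTC+).
    Events with no fold-change information are flagged 'undetermined'
    rather than dropped.
    """
    rows = []
    for ev in events:
        inc_ptc, skip_ptc = ptc_status.get(ev.event_id, (False, False))
        ptc_bearing = inc_ptc or skip_ptc
        gene = gene_of_event.get(ev.event_id)
        fcs = fold_changes.get(gene, {}) if gene else {}
        ejc_fcs = [fcs[c] for c in ejc_contrasts if c in fcs and pd.notna(fcs[c])]
        if ptc_bearing and not ejc_fcs:
            status = "undetermined"
        elif ptc_bearing and any(fc > fc_threshold for fc in ejc_fcs):
            status = "AS-NMD_candidate"
        elif ptc_bearing:
            status = "PTC_only"
        else:
            status = "no_PTC"
        rows.append(dict(
            event_id=ev.event_id, gene_id=gene,
            inclusion_ptc=inc_ptc, skipping_ptc=skip_ptc,
            ptc_bearing=ptc_bearing,
            max_ejc_fc=max(ejc_fcs) if ejc_fcs else float("nan"),
            status=status))
    return pd.DataFrame(rows, columns=["event_id", "gene_id", "inclusion_ptc",
                                       "skipping_ptc", "ptc_bearing",
                                       "max_ejc_fc", "status"])
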