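"""RNA splicing maps: positional CLIP-binding profiles around exons.

For each category of exons (skipping-up '+', inclusion-up '-', and the
control sets) the per-base CLIP coverage is divided by the mRNA
coverage at the same position (positions with zero mRNA are masked),
averaged over exons position-by-position (dividing by n(p), the number
of exons contributing an unmasked value at relative position p), and
finally scaled by the maximum over the analysed region so the profile
peaks at 1. Windows are the first and last ``width`` nt of each exon
(both kept in full for exons shorter than 2*width); intron maps anchor
the windows on the intronic side of the same borders.

This order of operations (per-exon ratio, per-position mean, global
max-scaling) makes the profile invariant to per-gene expression level
and to category size.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import CoverageTrack

REGIONS = ("upstream", "cassette", "downstream")
WINDOWS = ("five_prime", "three_prime")


@dataclass(frozen=True)
class BorderFrame:
    """Strand-aware window at one exon border.

    ``positions`` are genomic coordinates ordered along the transcript;
    ``rel`` is the relative axis: 1..m from the 5' border (five_prime
    window) or -m..-1 up to the 3' border (three_prime window, -1 = last
    exonic nt). Intronic frames use -m..-1 upstream of the 5' border and
    1..m downstream of the 3' border.
    """

    window: str
    positions: np.ndarray
    rel: np.ndarray


def extract_border_windows(start: int, end: int, strand: str,
                           width: int = 100) -> tuple[BorderFrame, BorderFrame]:
    """Exonic frames at the two borders of exon [start, end); exons
    shorter than ``width`` contribute only their existing positions."""
    length = end - start
    m = min(width, length)
    if strand == "+":
        five = np.arange(start, start + m)
        three = np.arange(end - m, end)
    else:
        five = np.arange(end - 1, end - 1 - m, -1)
        three = np.arange(start + m - 1, start - 1, -1)
    return (BorderFrame("five_prime", five, np.arange(1, m + 1)),
            BorderFrame("three_prime", three, np.arange(-m, 0)))


def extract_intron_windows(start: int, end: int, strand: str,
                           up_intron: int, dn_intron: int,
                           width: int = 100) -> tuple[BorderFrame, BorderFrame]:
    """Intronic frames flanking exon [start, end): the last ``width`` nt of
    the upstream intron (rel -m..-1 toward the 5' border) and the first
    ``width`` nt of the downstream intron (rel 1..m); introns shorter
    than ``width`` are truncated."""
    m_up = min(width, up_intron)
    m_dn = min(width, dn_intron)
    if strand == "+":
        five = np.arange(start - m_up, start)
        three = np.arange(end, end + m_dn)
    else:
        five = np.arange(end + m_up - 1, end - 1, -1)
        three = np.arange(start - 1, start - 1 - m_dn, -1)
    return (BorderFrame("five_prime", five, np.arange(-m_up, 0)),
            BorderFrame("three_prime", three, np.arange(1, m_dn + 1)))


def normalize_clip(clip: CoverageTrack, mrna: CoverageTrack,
                   chrom: str, strand: str, frame: BorderFrame) -> np.ndarray:
    """CLIP(p)/mRNA(p) over a frame; positions with mRNA(p) = 0 are NaN
    (excluded from sums and from n(p)), never infinite."""
    c = clip.at(chrom, strand, frame.positions)
    m = mrna.at(chrom, strand, frame.positions)
    out = np.full(len(c), np.nan)
    ok = m > 0
    out[ok] = c[ok] / m[ok]
    if len(out) and not ok.any():
        warnings.warn(f"{chrom}:{frame.positions.min()}-{frame.positions.max()}: "
                      "all positions masked (no mRNA coverage)", stacklevel=2)
    return out


@dataclass
class SplicingMapProfile:
    """Per-category profile: height H(p) in [0,1] (max over the analysed
    region = 1 when any signal is present) and exon support n(p)."""

    category: str
    table: pd.DataFrame  # columns: region, window, rel_pos, height, n


class _Accumulator:
    def __init__(self, width: int):
        self.width = width
        # rel axis per window: five_prime 1..w (exonic) or -w..w; use dicts
        self.sums: dict[tuple[str, str], dict[int, float]] = {}
        self.counts: dict[tuple[str, str], dict[int, int]] = {}

    def add(self, region: str, frame: BorderFrame, values: np.ndarray) -> None:
        key = (region, frame.window)
        s = self.sums.setdefault(key, {})
        n = self.counts.setdefault(key, {})
        for r, v in zip(frame.rel, values):
            if np.isnan(v):
                continue
            r = int(r)
            s[r] = s.get(r, 0.0) + v
            n[r] = n.get(r, 0) + 1

    def profile(self, category: str) -> SplicingMapProfile:
        rows = []
        for key in sorted(self.sums):
            region, window = key
            for r in sorted(self.sums[key]):
                n = self.counts[key][r]
                rows.append(dict(region=region, window=window, rel_pos=r,
                                 height=self.sums[key][r] / n, n=n))
        df = pd.DataFrame(rows, columns=["region", "window", "rel_pos", "height", "n"])
        peak = df["height"].max() if len(df) else 0.0
        if peak > 0:
            df["height"] = df["height"] / peak
        return SplicingMapProfile(category, df)


def _event_regions(ev):
    yield "upstream", ev.up_start, ev.up_end
    yield "cassette", ev.ca_start, ev.ca_end
    yield "downstream", ev.dn_start, ev.dn_end


def build_map(events_by_category: dict[str, list], clip: CoverageTrack,
              mrna: CoverageTrack, width: int = 100
              ) -> dict[str, SplicingMapProfile]:
    """Category-wise exonic splicing maps over the upstream, cassette and
    downstream exon borders; empty categories are omitted with a
    warning."""
    out = {}
    for category in sorted(events_by_category):
        events = events_by_category[category]
        if not events:
            warnings.warn(f"category {category!r} is empty; omitted", stacklevel=2)
            continue
        acc = _Accumulator(width)
        for ev in events:
            for region, start, end in _event_regions(ev):
                for frame in extract_border_windows(start, end, ev.strand, width):
                    vals = normalize_clip(clip, mrna, ev.chrom, ev.strand, frame)
                    acc.add(region, frame, vals)
        out[category] = acc.profile(category)
    return out


def build_intron_map(events_by_category: dict[str, list], clip: CoverageTrack,
                     mrna: CoverageTrack, width: int = 100
                     ) -> dict[str, SplicingMapProfile]:
    """Splicing maps over the introns flanking the cassette exon: the
    window on the intronic side of each cassette-exon border."""
    from .features import flank_lengths

    out = {}
    for category in sorted(events_by_category):
        events = events_by_category[category]
        if not events:
            warnings.warn(f"category {category!r} is empty; omitted", stacklevel=2)
            continue
        acc = _Accumulator(width)
        for ev in events:
            fl = flank_lengths(ev)
            if not fl.valid:
                continue
            frames = extract_intron_windows(ev.ca_start, ev.ca_end, ev.strand,
                                            fl.upstream_intron, fl.downstream_intron,
                                            width)
            for region, frame in zip(("upstream_intron", "downstream_intron"), frames):
                vals = normalize_clip(clip, mrna, ev.chrom, ev.strand, frame)
                acc.add(region, frame, vals)
        out[category] = acc.profile(category)
    return out


def profiles_to_dataframe(profiles: dict[str, SplicingMapProfile]) -> pd.DataFrame:
    frames = []
    for cat in sorted(profiles):
        df = profiles[cat].table.copy()
        df.insert(0, "category", cat)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["category", "region", "window",
                                     "rel_pos", "height", "n"])
    return pd.concat(frames, ignore_index=True)
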