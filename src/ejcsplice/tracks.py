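"""Per-base, strand-aware coverage tracks with bedGraph round-trip.

A track holds one dense non-negative array per (chromosome, strand);
queries outside covered regions return zeros. bedGraph carries no strand
column, so a stranded track is serialised as one file per strand.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np


class CoverageTrack:
    def __init__(self, chrom_sizes: dict[str, int]):
        self.chrom_sizes = dict(chrom_sizes)
        self._data: dict[tuple[str, str], np.ndarray] = {}

    def _arr(self, chrom: str, strand: str, create: bool = False) -> np.ndarray | None:
        key = (chrom, strand)
        if key not in self._data and create:
            self._data[key] = np.zeros(self.chrom_sizes[chrom], dtype=np.float64)
        return self._data.get(key)

    def add(self, chrom: str, strand: str, start: int, values: np.ndarray) -> None:
        arr = self._arr(chrom, strand, create=True)
        arr[start:start + len(values)] += values

    def get(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Values over [start, end); positions outside the chromosome or with
        no signal are 0."""
        out = np.zeros(end - start, dtype=np.float64)
        arr = self._arr(chrom, strand)
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, len(arr))
        if lo < hi:
            out[lo - start:hi - start] = arr[lo:hi]
        if (out < 0).any():
            raise ValueError("negative coverage")
        return out

    def at(self, chrom: str, strand: str, positions: np.ndarray) -> np.ndarray:
        arr = self._arr(chrom, strand)
        out = np.zeros(len(positions), dtype=np.float64)
        if arr is None:
            return out
        ok = (positions >= 0) & (positions < len(arr))
        out[ok] = arr[positions[ok]]
        return out

    def scale(self, factor: float) -> "CoverageTrack":
        t = CoverageTrack(self.chrom_sizes)
        for key, arr in self._data.items():
            t._data[key] = arr * factor
        return t

    # ---- bedGraph ----------------------------------------------------------

    def to_bedgraph(self, path: str | Path, strand: str) -> None:
        """Write one strand as bedGraph (0-based half-open, run-length rows;
        zero runs omitted)."""
        with open(path, "w") as fh:
            for chrom in sorted(self.chrom_sizes):
                arr = self._arr(chrom, strand)
                if arr is None:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                bounds = np.concatenate([[0], change, [len(arr)]])
                for s, e in zip(bounds[:-1], bounds[1:]):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")

    @classmethod
    def from_bedgraph(cls, paths: dict[str, str | Path],
                      chrom_sizes: dict[str, int]) -> "CoverageTrack":
        """Build a stranded track from {strand: bedgraph_path}."""
        track = cls(chrom_sizes)
        for strand, path in sorted(paths.items()):
            with open(path) as fh:
                for ln, line in enumerate(fh, 1):
                    line = line.strip()
                    if not line or line.startswith(("track", "#")):
                        continue
                    parts = line.split("\t")
                    if len(parts) != 4:
                        raise ValueError(f"{path}:{ln}: malformed bedGraph row")
                    chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                    if v < 0:
                        raise ValueError(f"{path}:{ln}: negative coverage")
                    track.add(chrom, strand, s, np.full(e - s, v))
        return track
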