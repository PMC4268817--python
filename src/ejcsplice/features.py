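"""Sequence and positional features of splicing events.

Covers splice-site strength (per-position log-odds models over the
standard 9-mer donor / 23-mer acceptor windows), splicing-regulatory
element (ESE/ESS/ISE/ISS) frequencies and composition-preserving
permutation z-scores, flanking intron/exon lengths, and the
rank-based group comparisons used throughout the analysis.

Scores are in bits: score(s) = sum_i log2(P_model[i, s_i] / P_bg[s_i]).
A model whose per-position probabilities equal the background scores 0
for every sequence, which anchors the scale.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .annotation import revcomp

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DONOR_LENGTH = 9       # last 3 exonic + first 6 intronic nt
ACCEPTOR_LENGTH = 23   # last 20 intronic + first 3 exonic nt

#: sentinel for undefined statistics (degenerate shuffles, constant input)
UNDEFINED = float("nan")

SRE_KMER = {"ESE": 6, "ESS": 6, "ISE": 6, "ISS": 10}


class SequenceError(ValueError):
    pass


def encode(seq: str) -> np.ndarray:
    """Map an ACGT string to an int8 array; rejects other symbols."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if (out < 0).any():
        bad = seq[int(np.argmax(out < 0))]
        raise SequenceError(f"non-ACGT symbol {bad!r} in sequence")
    return out


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer code of every length-k window (overlapping)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for i in range(k):
        out = out * 4 + codes[i:i + n].astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# Splicing regulatory elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifSet:
    """A named set of fixed-length splicing-regulatory motifs."""

    name: str
    kind: str            # ESE | ESS | ISE | ISS
    motifs: tuple[str, ...]
    _codes: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.kind not in SRE_KMER:
            raise SequenceError(f"unknown SRE kind {self.kind!r}")
        k = self.k
        ms = tuple(m.upper() for m in self.motifs)
        if len(set(ms)) != len(ms):
            raise SequenceError(f"{self.name}: duplicate motifs")
        for m in ms:
            if len(m) != k:
                raise SequenceError(f"{self.name}: motif {m!r} is not a {k}-mer")
        object.__setattr__(self, "motifs", ms)
        codes = np.sort(np.array([kmer_codes(encode(m), k)[0] for m in ms], dtype=np.int64)) \
            if ms else np.empty(0, dtype=np.int64)
        object.__setattr__(self, "_codes", codes)

    @property
    def k(self) -> int:
        return SRE_KMER[self.kind]

    def __len__(self) -> int:
        return len(self.motifs)

    @classmethod
    def from_file(cls, path: str | Path, kind: str, name: str | None = None) -> "MotifSet":
        """One motif per line; '#' lines are comments."""
        motifs = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                motifs.append(line)
        return cls(name or Path(path).stem, kind, tuple(motifs))

    @classmethod
    def bundled_synthetic(cls, kind: str) -> "MotifSet":
        """Synthetic stand-in motif set shipped with the package (the
        published screens' motif lists are not redistributed here)."""
        fname = f"synthetic_{kind.lower()}.txt"
        with resources.as_file(resources.files("ejcsplice.data") / fname) as p:
            return cls.from_file(p, kind, name=f"synthetic-{kind}")

    @classmethod
    def random(cls, kind: str, n: int, seed: int, name: str | None = None) -> "MotifSet":
        """Random motif set of the requested size (for simulations)."""
        rng = np.random.default_rng(seed)
        k = SRE_KMER[kind]
        motifs: set[str] = set()
        while len(motifs) < n:
            motifs.add("".join(rng.choice(list(BASES), size=k)))
        return cls(name or f"random-{kind}", kind, tuple(sorted(motifs)))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.motifs) + "\n")


def sre_count(seq: str, motifs: MotifSet) -> int:
    """Number of sliding-window positions whose k-mer is in the set;
    overlapping occurrences all count."""
    codes = kmer_codes(encode(seq), motifs.k)
    if len(codes) == 0:
        return 0
    return int(np.isin(codes, motifs._codes, assume_unique=False).sum())


def sre_frequency(seq: str, motifs: MotifSet) -> float:
    """Occurrences per nucleotide: count / len(seq).

    Sequences shorter than the motif length yield 0 with a warning.
    """
    if len(seq) == 0:
        raise SequenceError("empty sequence")
    if len(seq) < motifs.k:
        warnings.warn(f"sequence shorter than {motifs.k}-mer; frequency set to 0",
                      stacklevel=2)
        return 0.0
    return sre_count(seq, motifs) / len(seq)


def _mono_shuffle(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return rng.permutation(codes)


def _dinuc_shuffle(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Dinucleotide-composition-preserving shuffle (random Eulerian walk
    on the dinucleotide multigraph, with rejection until the chosen
    terminal edges leave the walk completable)."""
    if len(codes) < 3:
        return codes.copy()
    succ: dict[int, list[int]] = {}
    for a, b in zip(codes[:-1], codes[1:]):
        succ.setdefault(int(a), []).append(int(b))
    last = int(codes[-1])
    vertices = sorted(succ)
    for _ in range(1000):
        lasts = {}
        for v in vertices:
            if v == last:
                continue
            lasts[v] = succ[v][rng.integers(len(succ[v]))]
        # connectivity check: following chosen last edges from every vertex
        # must reach the terminal vertex
        ok = True
        for v in lasts:
            seen, cur = set(), v
            while cur != last:
                if cur in seen or cur not in lasts:
                    ok = False
                    break
                seen.add(cur)
                cur = lasts[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - rejection virtually always succeeds
        return rng.permutation(codes)
    shuffled: dict[int, list[int]] = {}
    for v in vertices:
        edges = list(succ[v])
        if v in lasts:
            edges.remove(lasts[v])
        rng.shuffle(edges)
        if v in lasts:
            edges.append(lasts[v])
        shuffled[v] = edges
    walk = [int(codes[0])]
    ptr = {v: 0 for v in vertices}
    while True:
        v = walk[-1]
        if v not in shuffled or ptr[v] >= len(shuffled[v]):
            break
        walk.append(shuffled[v][ptr[v]])
        ptr[v] += 1
    return np.array(walk, dtype=codes.dtype)


def motif_zscore(seq: str, motifs: MotifSet, n_shuffles: int = 100,
                 seed: int | None = None,
                 rng: np.random.Generator | None = None,
                 shuffle: str = "mono") -> float:
    """Permutation z-score of the motif frequency in ``seq``.

    The sequence is shuffled ``n_shuffles`` times preserving nucleotide
    composition (``shuffle='di'`` preserves dinucleotide composition);
    z = (f_obs - mean(f_shuffled)) / sd(f_shuffled). When the shuffle
    frequencies are all identical (sd = 0) the result is the NaN
    sentinel, never +/-inf.
    """
    if n_shuffles < 2:
        raise SequenceError("n_shuffles must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    codes = encode(seq)
    if len(codes) < motifs.k:
        return UNDEFINED
    shuf = _dinuc_shuffle if shuffle == "di" else _mono_shuffle
    f_obs = np.isin(kmer_codes(codes, motifs.k), motifs._codes).sum() / len(codes)
    freqs = np.empty(n_shuffles)
    for i in range(n_shuffles):
        c = shuf(codes, rng)
        freqs[i] = np.isin(kmer_codes(c, motifs.k), motifs._codes).sum() / len(c)
    sd = freqs.std(ddof=1)
    if sd == 0:
        return UNDEFINED
    return float((f_obs - freqs.mean()) / sd)


# ---------------------------------------------------------------------------
# Splice-site models
# ---------------------------------------------------------------------------

@dataclass
class SpliceSiteModel:
    """Independent per-position nucleotide probability model with a global
    background; ``score`` returns log2 odds in bits."""

    site_type: str                 # 'donor' | 'acceptor'
    probs: np.ndarray              # (k, 4), rows sum to 1
    background: np.ndarray         # (4,), sums to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        k = self.k
        if self.probs.shape != (k, 4):
            raise SequenceError(
                f"{self.site_type} model needs a ({k}, 4) matrix, got {self.probs.shape}")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise SequenceError("per-position probabilities must sum to 1")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise SequenceError("background must sum to 1")

    @property
    def k(self) -> int:
        if self.site_type == "donor":
            return DONOR_LENGTH
        if self.site_type == "acceptor":
            return ACCEPTOR_LENGTH
        raise SequenceError(f"unknown site type {self.site_type!r}")

    def score(self, seq: str) -> float:
        """log2(P_model / P_background) of a full-length site sequence."""
        codes = encode(seq)
        if len(codes) != self.k:
            raise SequenceError(
                f"{self.site_type} site must be a {self.k}-mer, got {len(codes)} nt")
        p = self.probs[np.arange(self.k), codes]
        q = self.background[codes]
        with np.errstate(divide="ignore"):
            return float(np.sum(np.log2(p) - np.log2(q)))

    def sample(self, n: int, rng: np.random.Generator) -> list[str]:
        cum = np.cumsum(self.probs, axis=1)
        u = rng.random((n, self.k))
        idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
        lut = np.array(list(BASES))
        return ["".join(row) for row in lut[idx]]

    def save(self, path: str | Path) -> None:
        lines = [f"# splice-site model\t{self.site_type}",
                 "\t".join(["background"] + [f"{v:.10g}" for v in self.background])]
        for i, row in enumerate(self.probs):
            lines.append("\t".join([str(i)] + [f"{v:.10g}" for v in row]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SpliceSiteModel":
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("# splice-site model"):
            raise SequenceError(f"{path}: not a splice-site model table")
        site_type = lines[0].split("\t")[1]
        background = np.array([float(x) for x in lines[1].split("\t")[1:]])
        probs = np.array([[float(x) for x in ln.split("\t")[1:]] for ln in lines[2:] if ln])
        return cls(site_type, probs, background)


def score_site(seq: str, model: SpliceSiteModel) -> float:
    """Log-odds score (bits) of a site sequence under a model; the
    sequence length must match the model's site type."""
    return model.score(seq)


def train_site_model(seqs: Sequence[str], site_type: str,
                     pseudocount: float = 0.5,
                     background: np.ndarray | None = None) -> SpliceSiteModel:
    """Fit per-position nucleotide probabilities with an additive
    pseudocount; the background defaults to the global composition of the
    training set (with the same pseudocount)."""
    k = DONOR_LENGTH if site_type == "donor" else ACCEPTOR_LENGTH
    if len(seqs) == 0:
        raise SequenceError("empty training set")
    counts = np.zeros((k, 4))
    for s in seqs:
        codes = encode(s)
        if len(codes) != k:
            raise SequenceError(f"{site_type} training sequence must be {k} nt, got {len(codes)}")
        counts[np.arange(k), codes] += 1
    counts += pseudocount
    probs = counts / counts.sum(axis=1, keepdims=True)
    if background is None:
        total = counts.sum(axis=0)
        background = total / total.sum()
    return SpliceSiteModel(site_type, probs, np.asarray(background, dtype=float))


def load_site_models(directory: str | Path) -> dict[str, SpliceSiteModel]:
    """Load donor/acceptor score tables from ``directory``.

    Expects ``donor.tsv`` and ``acceptor.tsv`` in the package's plain-text
    model layout (see :meth:`SpliceSiteModel.save`). The maximum-entropy
    score tables distributed with external splice-site scorers are not
    bundled; when no tables are found, a clear error points at
    :func:`train_site_model` / the built-in canonical models instead.
    """
    directory = Path(directory)
    out = {}
    for site in ("donor", "acceptor"):
        p = directory / f"{site}.tsv"
        if not p.exists():
            raise FileNotFoundError(
                f"no {site} score table at {p}; external maximum-entropy tables are "
                "not bundled - train a model with train_site_model() or use "
                "default_donor_model()/default_acceptor_model()")
        out[site] = SpliceSiteModel.load(p)
    return out


# canonical-like position probabilities used for simulation defaults.
# Donor window: exon positions -3..-1 then intron +1..+6 (consensus CAG|GTAAGT).
_DONOR_P = np.array([
    [0.33, 0.37, 0.18, 0.12],
    [0.60, 0.13, 0.14, 0.13],
    [0.09, 0.04, 0.80, 0.07],
    [0.00, 0.00, 1.00, 0.00],
    [0.00, 0.01, 0.00, 0.99],
    [0.60, 0.02, 0.35, 0.03],
    [0.70, 0.08, 0.11, 0.11],
    [0.07, 0.06, 0.82, 0.05],
    [0.17, 0.19, 0.19, 0.45],
])
# Acceptor window: intron -20..-1 (branch/polypyrimidine tract, then AG)
# followed by exon +1..+3.
_ACCEPTOR_P = np.vstack([
    np.tile([0.10, 0.31, 0.13, 0.46], (17, 1)),
    [[0.05, 0.65, 0.05, 0.25],    # -3 (pyrimidine, mostly C)
     [0.99, 0.00, 0.00, 0.01],    # -2 A
     [0.00, 0.00, 1.00, 0.00],    # -1 G
     [0.25, 0.15, 0.50, 0.10],    # +1
     [0.27, 0.22, 0.26, 0.25],
     [0.24, 0.26, 0.26, 0.24]],
])
_UNIFORM_BG = np.full(4, 0.25)


def default_donor_model() -> SpliceSiteModel:
    """Canonical-like human donor (5'ss) position model over 9-mers."""
    return SpliceSiteModel("donor", _DONOR_P, _UNIFORM_BG.copy())


def default_acceptor_model() -> SpliceSiteModel:
    """Canonical-like human acceptor (3'ss) position model over 23-mers."""
    return SpliceSiteModel("acceptor", _ACCEPTOR_P, _UNIFORM_BG.copy())


# ---------------------------------------------------------------------------
# Site sequence extraction
# ---------------------------------------------------------------------------

def donor_site_seq(genome: dict[str, str], chrom: str, strand: str,
                   start: int, end: int) -> str:
    """9-mer around the donor (5') splice site of exon [start, end):
    last 3 exonic + first 6 downstream-intronic nt, transcript orientation."""
    seq = genome[chrom]
    if strand == "+":
        return seq[end - 3:end + 6].upper()
    return revcomp(seq[start - 6:start + 3]).upper()


def acceptor_site_seq(genome: dict[str, str], chrom: str, strand: str,
                      start: int, end: int) -> str:
    """23-mer around the acceptor (3') splice site of exon [start, end):
    last 20 upstream-intronic + first 3 exonic nt, transcript orientation."""
    seq = genome[chrom]
    if strand == "+":
        return seq[start - 20:start + 3].upper()
    return revcomp(seq[end - 3:end + 20]).upper()


# ---------------------------------------------------------------------------
# Lengths and group statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlankLengths:
    upstream_intron: int
    downstream_intron: int
    upstream_exon: int
    cassette_exon: int
    downstream_exon: int
    valid: bool


def flank_lengths(event) -> FlankLengths:
    """Intron and exon lengths of a cassette-exon trio, strand-aware
    (upstream = 5' side of the transcript). Non-positive gaps flag the
    event invalid rather than raising."""
    if event.strand == "+":
        up_intron = event.ca_start - event.up_end
        dn_intron = event.dn_start - event.ca_end
    else:
        up_intron = event.up_start - event.ca_end
        dn_intron = event.ca_start - event.dn_end
    valid = up_intron > 0 and dn_intron > 0
    return FlankLengths(
        upstream_intron=up_intron,
        downstream_intron=dn_intron,
        upstream_exon=event.up_end - event.up_start,
        cassette_exon=event.ca_end - event.ca_start,
        downstream_exon=event.dn_end - event.dn_start,
        valid=valid,
    )


def compare_groups(values_a: Iterable[float], values_b: Iterable[float]):
    """Mann-Whitney-Wilcoxon rank-sum test, two-sided.

    Exact enumeration for small tie-free samples, normal approximation
    otherwise (scipy's 'auto' policy). Returns (U statistic, p-value).
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise SequenceError("empty group in comparison")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def length_expression_correlation(lengths: Iterable[float],
                                  log_fold_changes: Iterable[float]):
    """Spearman rank correlation (tie-corrected) between intron length and
    differential expression; constant input yields the NaN sentinel."""
    x = np.asarray(list(lengths), dtype=float)
    y = np.asarray(list(log_fold_changes), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise SequenceError("need >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return UNDEFINED, UNDEFINED
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
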