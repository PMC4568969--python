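"""Position-weight-matrix motifs, promoter windows, and conservation weighting.

A :class:`MotifModel` wraps a JASPAR-style position frequency matrix and
derives a log-odds (bits) scoring matrix under a background base
composition with a proportional pseudocount.  Sequences are scored on both
strands; each gene is summarised by its best conservation-weighted site
inside a TSS-centred window (by default −10 kb .. +10 kb).  Conservation is
consumed from pre-aligned ortholog sequences as a per-position identity
fraction; with no orthologs the profile is all ones and scoring reduces to
an unweighted PWM scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "MotifModel",
    "PromoterWindow",
    "MotifHit",
    "GeneMotifScore",
    "read_jaspar",
    "write_jaspar",
    "read_tss_bed",
    "extract_window",
    "scan_sequence",
    "conservation_profile",
    "gene_motif_score",
    "reverse_complement",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

#: default uniform background composition
UNIFORM_BACKGROUND = np.full(4, 0.25)
#: default total pseudocount, distributed proportionally to the background
DEFAULT_PSEUDOCOUNT = 0.8


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes (A=0 C=1 G=2 T=3, anything else −1)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class MotifModel:
    """A transcription-factor binding motif as counts plus derived log-odds.

    ``logodds[b, i] = log2(((counts[b,i] + pseudocount*background[b]) /
    (colsum_i + pseudocount)) / background[b])`` — i.e. the pseudocount is
    shared across the column proportionally to the background, and scores
    are in bits relative to that background.
    """

    motif_id: str
    name: str
    counts: np.ndarray  # 4 × L, rows A,C,G,T
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError(f"motif {self.motif_id}: counts must have 4 rows (A,C,G,T)")
        if self.length < 4:
            raise ValueError(f"motif {self.motif_id}: length {self.length} < 4")
        if (self.counts < 0).any():
            raise ValueError(f"motif {self.motif_id}: negative counts")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @cached_property
    def logodds(self) -> np.ndarray:
        """4 × L log-odds matrix in bits."""
        colsum = self.counts.sum(axis=0)
        freq = (self.counts + self.pseudocount * self.background[:, None]) / (
            colsum + self.pseudocount
        )
        return np.log2(freq / self.background[:, None])

    @property
    def max_score(self) -> float:
        """Best attainable score: the sum of per-column log-odds maxima."""
        return float(self.logodds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass
class PromoterWindow:
    """A TSS-centred genomic window, 5'→3' relative to gene orientation."""

    gene: str
    contig: str
    tss: int  # 0-based
    strand: str
    upstream_bp: int
    downstream_bp: int
    sequence: str
    genomic_start: int = 0  # start of the window on the forward contig

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.sequence) > self.upstream_bp + self.downstream_bp:
            raise ValueError("window sequence longer than upstream+downstream span")


@dataclass(frozen=True)
class MotifHit:
    offset: int
    strand_of_hit: str
    score: float
    conservation_weight: float = 1.0


@dataclass(frozen=True)
class GeneMotifScore:
    """One gene's aggregate conservation-weighted motif score (bits)."""

    gene: str
    motif_id: str
    score: float


# ---------------------------------------------------------------------------
# JASPAR PFM text I/O
# ---------------------------------------------------------------------------

def read_jaspar(
    path,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
) -> list[MotifModel]:
    """Parse JASPAR PFM text: ``>`` headers, then 4 count rows per record.

    Both common dialects are accepted: bare whitespace-separated counts in
    A,C,G,T order, or rows prefixed with the base letter and counts inside
    brackets (``A [ 4 19 0 ]``).
    """
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    motifs: list[MotifModel] = []
    header: str | None = None
    rows: list[tuple[str | None, list[float]]] = []

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        parts = header[1:].split(None, 1)
        motif_id = parts[0] if parts else "motif"
        name = parts[1].strip() if len(parts) > 1 else motif_id
        if len(rows) != 4:
            raise ValueError(f"motif {motif_id}: expected 4 count rows, got {len(rows)}")
        if all(label is not None for label, _ in rows):
            by_base = {label: vals for label, vals in rows}
            if set(by_base) != set(BASES):
                raise ValueError(f"motif {motif_id}: rows must cover A,C,G,T")
            ordered = [by_base[b] for b in BASES]
        else:
            ordered = [vals for _, vals in rows]
        lengths = {len(v) for v in ordered}
        if len(lengths) != 1:
            raise ValueError(f"motif {motif_id}: row lengths differ ({sorted(lengths)})")
        counts = np.array(ordered, dtype=float)
        if (counts < 0).any():
            raise ValueError(f"motif {motif_id}: negative counts")
        motifs.append(
            MotifModel(motif_id=motif_id, name=name, counts=counts,
                       pseudocount=pseudocount, background=bg.copy())
        )
        header, rows = None, []

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line
                continue
            label: str | None = None
            body = line
            if body[0].upper() in BASES and (len(body) == 1 or not body[1].isdigit() or body[1].isspace()):
                first, _, rest = body.partition(" ")
                if first.upper() in BASES and len(first) == 1:
                    label, body = first.upper(), rest
            body = body.replace("[", " ").replace("]", " ")
            vals = [float(tok) for tok in body.split()]
            rows.append((label, vals))
    flush()
    return motifs


def write_jaspar(motifs: Iterable[MotifModel], path) -> None:
    """Write motifs in the letter-labelled bracketed JASPAR dialect."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id} {m.name}\n")
            for b, row in zip(BASES, m.counts):
                fh.write(f"{b} [ " + " ".join(f"{v:g}" for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# Promoter windows
# ---------------------------------------------------------------------------

def read_tss_bed(path) -> pd.DataFrame:
    """Read a BED-like TSS table: chrom, start(=TSS), end, gene, score, strand."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["contig", "tss", "end", "gene", "score", "strand"],
        dtype={"contig": str, "gene": str, "strand": str},
    )
    return df[["contig", "tss", "gene", "strand"]]


def _contig_length(genome, contig: str) -> int:
    return len(genome[contig])


def _fetch(genome, contig: str, start: int, end: int) -> str:
    return str(genome[contig][start:end]).upper()


def extract_window(
    tss_table: pd.DataFrame,
    genome: Mapping[str, str],
    upstream_bp: int = 10_000,
    downstream_bp: int = 10_000,
) -> list[PromoterWindow]:
    """Cut TSS-centred windows out of a genome (dict-like or pyfaidx.Fasta).

    Plus-strand genes take the half-open interval
    ``[tss − upstream, tss + downstream)``; minus-strand genes take
    ``[tss − downstream, tss + upstream)`` reverse-complemented, so the
    returned sequence always reads 5'→3' along the gene with ``upstream_bp``
    bases before the TSS.  Intervals are clipped to contig bounds with a
    warning.
    """
    windows = []
    for row in tss_table.itertuples(index=False):
        contig, tss, gene, strand = str(row.contig), int(row.tss), str(row.gene), str(row.strand)
        try:
            clen = _contig_length(genome, contig)
        except KeyError:
            raise KeyError(f"unknown contig {contig!r} for gene {gene}") from None
        if not 0 <= tss < clen:
            raise ValueError(f"gene {gene}: TSS {tss} outside contig {contig} (length {clen})")
        if strand == "+":
            start, end = tss - upstream_bp, tss + downstream_bp
        elif strand == "-":
            start, end = tss - downstream_bp, tss + upstream_bp
        else:
            raise ValueError(f"gene {gene}: strand must be + or -, got {strand!r}")
        cstart, cend = max(start, 0), min(end, clen)
        if (cstart, cend) != (start, end):
            warnings.warn(f"gene {gene}: window [{start},{end}) clipped to [{cstart},{cend})")
        seq = _fetch(genome, contig, cstart, cend)
        if strand == "-":
            seq = reverse_complement(seq)
        windows.append(
            PromoterWindow(
                gene=gene, contig=contig, tss=tss, strand=strand,
                upstream_bp=upstream_bp, downstream_bp=downstream_bp,
                sequence=seq, genomic_start=cstart,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# Scanning and scoring
# ---------------------------------------------------------------------------

def _strand_scores(codes: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset; offsets overlapping N score −inf."""
    L = logodds.shape[1]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    win = sliding_window_view(codes, L)
    valid = (win >= 0).all(axis=1)
    scores = np.full(n, -np.inf)
    if valid.any():
        idx = win[valid].astype(np.intp)
        scores[valid] = logodds[idx, np.arange(L)].sum(axis=1)
    return scores


def _both_strand_scores(seq: str, motif: MotifModel) -> tuple[np.ndarray, np.ndarray]:
    codes = encode(seq)
    lo = motif.logodds
    fwd = _strand_scores(codes, lo)
    # reverse complement of the L-mer == scan forward with the rc'd PWM:
    # complement rows (A<->T, C<->G == reversed A,C,G,T order), reversed columns
    rev = _strand_scores(codes, lo[::-1, ::-1])
    return fwd, rev


def scan_sequence(
    window: PromoterWindow | str,
    motif: MotifModel,
    threshold: float,
    profile: np.ndarray | None = None,
) -> list[MotifHit]:
    """Report every offset/strand scoring at least *threshold* bits.

    Offsets are 0-based positions of the site's leftmost base on the given
    sequence; minus-strand hits score the reverse complement of the L-mer at
    that offset.  Positions overlapping N never score.
    """
    seq = window.sequence if isinstance(window, PromoterWindow) else window
    fwd, rev = _both_strand_scores(seq, motif)
    L = motif.length
    if profile is not None:
        meanw = _site_mean_weights(np.asarray(profile, float), L, len(seq))
    hits = []
    for strand, scores in (("+", fwd), ("-", rev)):
        for off in np.nonzero(np.isfinite(scores) & (scores >= threshold))[0]:
            w = float(meanw[off]) if profile is not None else 1.0
            hits.append(MotifHit(int(off), strand, float(scores[off]), w))
    hits.sort(key=lambda h: (h.offset, h.strand_of_hit))
    return hits


def conservation_profile(
    window: PromoterWindow | str,
    orthologs: Sequence[str],
) -> np.ndarray:
    """Per-position identity fraction of ortholog bases to the window base.

    Gaps and N in an ortholog count as mismatch.  With no orthologs the
    profile is all ones (unweighted fallback).
    """
    seq = window.sequence if isinstance(window, PromoterWindow) else window
    n = len(seq)
    if not orthologs:
        return np.ones(n)
    ref = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    ref_valid = encode(seq) >= 0
    matches = np.zeros(n)
    for orth in orthologs:
        if len(orth) != n:
            raise ValueError(f"ortholog length {len(orth)} != window length {n}")
        o = np.frombuffer(orth.upper().encode(), dtype=np.uint8)
        matches += (o == ref) & ref_valid & (encode(orth) >= 0)
    return matches / len(orthologs)


def _site_mean_weights(profile: np.ndarray, L: int, seqlen: int) -> np.ndarray:
    """Mean conservation weight over every length-L site span."""
    if len(profile) != seqlen:
        raise ValueError(f"profile length {len(profile)} != sequence length {seqlen}")
    n = seqlen - L + 1
    if n <= 0:
        return np.empty(0)
    cs = np.concatenate(([0.0], np.cumsum(profile)))
    return (cs[L:] - cs[:-L]) / L


def gene_motif_score(
    window: PromoterWindow | str,
    motif: MotifModel,
    profile: np.ndarray | None = None,
    top_k: int = 1,
) -> GeneMotifScore:
    """Aggregate a window into one conservation-weighted motif score.

    Every offset/strand gets ``site log-odds × mean conservation weight over
    the site span``; the gene score is the best such value (or, with
    ``top_k > 1``, the sum of the top k positive values — a sensitivity
    option).  Windows with no positive-scoring site score 0.
    """
    seq = window.sequence if isinstance(window, PromoterWindow) else window
    gene = window.gene if isinstance(window, PromoterWindow) else ""
    fwd, rev = _both_strand_scores(seq, motif)
    if fwd.size == 0:
        return GeneMotifScore(gene, motif.motif_id, 0.0)
    if profile is None:
        meanw = np.ones(fwd.size)
    else:
        meanw = _site_mean_weights(np.asarray(profile, float), motif.length, len(seq))
    weighted = []
    for scores in (fwd, rev):
        w = np.full_like(scores, -np.inf)
        mask = np.isfinite(scores)
        w[mask] = scores[mask] * meanw[mask]
        weighted.append(w)
    allw = np.concatenate(weighted)
    positive = allw[allw > 0]
    if positive.size == 0:
        return GeneMotifScore(gene, motif.motif_id, 0.0)
    if top_k <= 1:
        return GeneMotifScore(gene, motif.motif_id, float(positive.max()))
    top = np.sort(positive)[::-1][:top_k]
    return GeneMotifScore(gene, motif.motif_id, float(top.sum()))
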