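"""Promoter dissection: consensus sites, tandem pairs, conservation, mutants.

Works on a single promoter region — typically a short bidirectional
promoter shared by two divergently transcribed genes — given as a forward
genomic sequence.  IUPAC consensus patterns (e.g. the NRF-2/GABP core
CCGGAA) are matched exactly on both strands; closely spaced co-oriented
site pairs are flagged as tandems; a multi-species alignment is summarised
as a per-column identity profile with the best-conserved window; and two
reporter-mutant designs are supported: a per-site substitution (e.g. the
CCGGAA → CCTTAA double transversion) and deletion of a tandem pair with its
intervening spacer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ConsensusPattern",
    "Site",
    "TandemPair",
    "MutantDesign",
    "ConservationReport",
    "find_consensus_sites",
    "find_tandem_pairs",
    "design_double_transversion",
    "design_deletion",
    "conservation_report",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp_iupac(pattern: str) -> str:
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConsensusPattern:
    """An exact-match IUPAC consensus, optionally searched on both strands."""

    pattern: str
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty consensus pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in pattern: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.pattern)

    def regex(self, reverse: bool = False) -> re.Pattern:
        pat = _revcomp_iupac(self.pattern.upper()) if reverse else self.pattern.upper()
        # character classes over A,C,G,T only — an N in the sequence never matches
        body = "".join(f"[{IUPAC[c]}]" for c in pat)
        return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


class Site(NamedTuple):
    offset: int
    strand: str


@dataclass(frozen=True)
class TandemPair:
    """Two non-overlapping co-oriented sites and their spacing."""

    first_site: Site
    second_site: Site
    spacer_bp: int
    span_bp: int


@dataclass
class MutantDesign:
    """An edit applied to a promoter, with before/after consensus counts."""

    kind: str  # "substitution" | "deletion"
    sequence_before: str
    sequence_after: str
    edits: list[tuple[int, str, str]] = field(default_factory=list)
    deleted_span: tuple[int, int] | None = None
    sites_before: int = 0
    sites_after: int = 0

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if len(self.sequence_after) != len(self.sequence_before):
                raise ValueError("substitution must preserve sequence length")
        elif self.kind == "deletion":
            start, end = self.deleted_span
            if len(self.sequence_after) != len(self.sequence_before) - (end - start):
                raise ValueError("deletion length inconsistent with deleted span")
        else:
            raise ValueError(f"unknown design kind {self.kind!r}")


def find_consensus_sites(sequence: str, pattern: ConsensusPattern | str) -> list[Site]:
    """All exact IUPAC matches of the pattern; offsets on the forward strand.

    Minus-strand sites are matches of the reverse-complemented pattern in
    the forward sequence, reported at their forward-strand offset.  N in the
    sequence never matches any code.
    """
    if isinstance(pattern, str):
        pattern = ConsensusPattern(pattern)
    seq = sequence.upper()
    sites = [Site(m.start(), "+") for m in pattern.regex().finditer(seq)]
    if pattern.both_strands:
        # a palindromic pattern matches both strands at one offset; both kept
        rev = pattern.regex(reverse=True)
        sites.extend(Site(m.start(), "-") for m in rev.finditer(seq))
    sites.sort(key=lambda s: (s.offset, s.strand))
    return sites


def find_tandem_pairs(
    sites: Sequence[Site],
    pattern_length: int,
    max_spacer_bp: int = 50,
) -> list[TandemPair]:
    """Every ordered pair of non-overlapping co-oriented sites within range.

    ``spacer_bp`` is the gap between the first site's end and the second
    site's start; ``span_bp`` runs from the first site's start to the second
    site's end, so co-oriented non-overlapping pairs satisfy
    ``span = 2·L + spacer``.
    """
    ordered = sorted(sites, key=lambda s: (s.offset, s.strand))
    pairs = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if b.strand != a.strand:
                continue
            spacer = b.offset - (a.offset + pattern_length)
            if spacer < 0:  # overlapping
                continue
            if spacer > max_spacer_bp:
                continue
            pairs.append(
                TandemPair(
                    first_site=a,
                    second_site=b,
                    spacer_bp=spacer,
                    span_bp=(b.offset + pattern_length) - a.offset,
                )
            )
    return pairs


def _matches_iupac(segment: str, pattern: str) -> bool:
    return len(segment) == len(pattern) and all(
        s in IUPAC[p] for s, p in zip(segment.upper(), pattern.upper())
    )


def design_double_transversion(
    sequence: str,
    sites: Sequence[Site],
    from_pattern: str = "CCGGAA",
    to_pattern: str = "CCTTAA",
) -> MutantDesign:
    """Substitute every listed site from one consensus core to another.

    The canonical use is ablating NRF-2/GABP cores by the CCGGAA → CCTTAA
    double transversion (two G→T changes per site).  Minus-strand sites are
    edited through the reverse complement of both patterns on the forward
    sequence.  Each changed base is recorded as (position, from, to); site
    counts before/after come from re-scanning with the original pattern.
    """
    if len(from_pattern) != len(to_pattern):
        raise ValueError("from/to patterns must have equal length")
    L = len(from_pattern)
    seq = list(sequence.upper())
    edits: list[tuple[int, str, str]] = []
    for site in sites:
        fp = from_pattern if site.strand == "+" else _revcomp_iupac(from_pattern)
        tp = to_pattern if site.strand == "+" else _revcomp_iupac(to_pattern)
        segment = "".join(seq[site.offset: site.offset + L])
        if not _matches_iupac(segment, fp):
            raise ValueError(
                f"site at offset {site.offset} ({site.strand}) does not match "
                f"{from_pattern} (found {segment})"
            )
        for j, new in enumerate(tp):
            old = seq[site.offset + j]
            if old != new:
                edits.append((site.offset + j, old, new))
                seq[site.offset + j] = new
    mutant = "".join(seq)
    pattern = ConsensusPattern(from_pattern)
    return MutantDesign(
        kind="substitution",
        sequence_before=sequence,
        sequence_after=mutant,
        edits=edits,
        sites_before=len(find_consensus_sites(sequence, pattern)),
        sites_after=len(find_consensus_sites(mutant, pattern)),
    )


def design_deletion(
    sequence: str,
    pair: TandemPair,
    pattern: ConsensusPattern | str | None = None,
) -> MutantDesign:
    """Delete a tandem site pair plus its intervening spacer.

    Removes the half-open span from the first site's start to the second
    site's end (for the promoter's tandem NRF-2 pair: 6 + 14 + 6 = 26
    bases).  Site counts are re-scanned with *pattern* when given.
    """
    start = pair.first_site.offset
    end = start + pair.span_bp
    if not (0 <= start < end <= len(sequence)):
        raise ValueError(f"deletion span [{start},{end}) outside sequence of length {len(sequence)}")
    mutant = sequence[:start] + sequence[end:]
    before = after = 0
    if pattern is not None:
        before = len(find_consensus_sites(sequence, pattern))
        after = len(find_consensus_sites(mutant, pattern))
    return MutantDesign(
        kind="deletion",
        sequence_before=sequence,
        sequence_after=mutant,
        deleted_span=(start, end),
        sites_before=before,
        sites_after=after,
    )


@dataclass
class ConservationReport:
    """Per-column identity to the reference plus the best-conserved window."""

    identity: np.ndarray  # per-column fraction of non-reference sequences matching
    window_width: int
    window_means: np.ndarray
    best_window_start: int

    @property
    def best_window_mean(self) -> float:
        return float(self.window_means[self.best_window_start])


def conservation_report(
    sequences: Mapping[str, str] | Sequence[str],
    window_width: int,
    reference: str | None = None,
) -> ConservationReport:
    """Column-wise identity of an aligned promoter block across species.

    The first sequence (or the one named by *reference* when a mapping is
    given) is the reference; identity at a column is the fraction of the
    other sequences whose base matches it (gap/N mismatch).  The report
    includes the sliding mean over *window_width* columns and the leftmost
    argmax window.
    """
    if isinstance(sequences, Mapping):
        names = list(sequences)
        ref_name = reference if reference is not None else names[0]
        ref = sequences[ref_name]
        others = [sequences[n] for n in names if n != ref_name]
    else:
        seqs = list(sequences)
        ref = seqs[0]
        others = seqs[1:]
    if not others:
        raise ValueError("conservation requires at least 2 aligned sequences")
    n = len(ref)
    for s in others:
        if len(s) != n:
            raise ValueError("aligned sequences must have equal length")
    if not 1 <= window_width <= n:
        raise ValueError("window width must be in [1, alignment length]")

    ref_u = np.frombuffer(ref.upper().encode(), dtype=np.uint8)
    valid = np.isin(ref_u, np.frombuffer(b"ACGT", dtype=np.uint8))
    matches = np.zeros(n)
    for s in others:
        su = np.frombuffer(s.upper().encode(), dtype=np.uint8)
        s_valid = np.isin(su, np.frombuffer(b"ACGT", dtype=np.uint8))
        matches += (su == ref_u) & valid & s_valid
    identity = matches / len(others)

    cs = np.concatenate(([0.0], np.cumsum(identity)))
    window_means = (cs[window_width:] - cs[:-window_width]) / window_width
    best = int(np.argmax(window_means))  # argmax → leftmost on ties
    return ConservationReport(
        identity=identity,
        window_width=window_width,
        window_means=window_means,
        best_window_start=best,
    )
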