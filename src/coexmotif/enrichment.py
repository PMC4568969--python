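"""AUC enrichment of gene sets over motif scores, with permutation nulls.

The enrichment statistic is the area under the ROC curve: the probability
that a randomly chosen foreground (gene-set) gene out-scores a randomly
chosen background gene, with ties counted half (Mann–Whitney midrank
formula).  Significance comes from a permutation null of random gene sets
of matched size drawn from the scored universe; q-values are
Benjamini–Hochberg within each analysis across the motif family.  A run
over several gene-set sizes and tracks is summarised as a heat-map table
ordered by each motif's maximum AUC, plus cross-analysis overlap reports.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "OverlapSummary",
    "compute_auc",
    "enrichment_test",
    "bh_qvalues",
    "run_matrix",
    "overlap_summary",
    "results_to_frame",
    "TIER_NONE",
    "TIER_05",
    "TIER_01",
]

TIER_NONE = ""
TIER_05 = "q<0.05"
TIER_01 = "q<0.01"


@dataclass(frozen=True)
class EnrichmentResult:
    """Per (motif, gene set) enrichment outcome."""

    motif_id: str
    set_name: str
    auc: float
    p_value: float
    q_value: float
    tier: str = TIER_NONE

    def __post_init__(self) -> None:
        if self.q_value < self.p_value - 1e-12:
            raise ValueError("q-value cannot be below its p-value")


def _tier(q: float, fdr: float = 0.05, strict_fdr: float = 0.01) -> str:
    if q < strict_fdr:
        return TIER_01
    if q < fdr:
        return TIER_05
    return TIER_NONE


def compute_auc(fg_scores: Sequence[float], bg_scores: Sequence[float]) -> float:
    """P(random foreground score > random background score) + ½·P(tie).

    Computed by the midrank (Mann–Whitney U) formula; equals exhaustive
    pair counting for any inputs.
    """
    fg = np.asarray(fg_scores, dtype=float)
    bg = np.asarray(bg_scores, dtype=float)
    if fg.size == 0 or bg.size == 0:
        raise ValueError("compute_auc needs non-empty foreground and background")
    ranks = rankdata(np.concatenate([fg, bg]))
    r_fg = ranks[: fg.size].sum()
    u = r_fg - fg.size * (fg.size + 1) / 2
    return float(u / (fg.size * bg.size))


def _auc_from_rank_sum(rank_sum, k: int, m: int):
    return (rank_sum - k * (k + 1) / 2) / (k * m)


def enrichment_test(
    scores: Mapping[str, float] | pd.Series,
    gene_set,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """AUC of a gene set against the rest of the universe, with permutation p.

    The null is random gene sets of identical size drawn uniformly without
    replacement from the scored universe; ``p = (1 + #{null AUC ≥ observed})
    / (n_perm + 1)``, so p is never below ``1/(n_perm+1)``.  With
    ``exhaustive=True`` every subset of the universe of the set's size is
    enumerated instead (feasible only for tiny universes) and ``n_perm`` is
    ignored.

    Parameters are seed-deterministic: the same ``seed`` (or ``rng`` state)
    reproduces the p-value bit for bit.
    """
    series = pd.Series(scores, dtype=float) if not isinstance(scores, pd.Series) else scores
    members = list(gene_set.members) if hasattr(gene_set, "members") else list(gene_set)
    missing = [g for g in members if g not in series.index]
    if missing:
        raise KeyError(f"gene set members without scores: {missing[:5]}")
    n = series.size
    k = len(members)
    if k >= n:
        raise ValueError("gene set must be a strict subset of the scored universe")

    ranks = rankdata(series.to_numpy())
    in_set = series.index.isin(members)
    m = n - k
    obs_auc = float(_auc_from_rank_sum(ranks[in_set].sum(), k, m))

    if exhaustive:
        null = np.array(
            [
                _auc_from_rank_sum(ranks[list(combo)].sum(), k, m)
                for combo in itertools.combinations(range(n), k)
            ]
        )
    else:
        if rng is None:
            if seed is None:
                raise ValueError("enrichment_test requires a seed (or rng) for the permutation null")
            rng = np.random.default_rng(seed)
        null = _null_auc_samples(ranks, k, n_perm, rng)
    p = (1 + int((null >= obs_auc - 1e-12).sum())) / (null.size + 1)
    return obs_auc, float(p)


def _null_auc_samples(ranks: np.ndarray, k: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """AUCs of n_perm uniform random k-subsets of the universe."""
    n = ranks.size
    u = rng.random((n_perm, n))
    idx = np.argpartition(u, k - 1, axis=1)[:, :k]
    sums = ranks[idx].sum(axis=1)
    return _auc_from_rank_sum(sums, k, n - k)


def bh_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_matrix(
    scores: pd.DataFrame,
    gene_sets: Sequence,
    n_perm: int = 1000,
    seed: int = 0,
    fdr: float = 0.05,
    strict_fdr: float = 0.01,
    top: int = 10,
) -> tuple[list[EnrichmentResult], pd.DataFrame]:
    """Enrich every motif against every gene set and build the summary table.

    Parameters
    ----------
    scores
        Motifs × genes score matrix (one row per motif over a shared
        universe; NaN marks an unscored gene and is rejected).
    gene_sets
        Gene sets (each with ``name`` and ``members``); in the standard
        configuration 3 sizes × 2 tracks.

    Returns the full per-(analysis, motif) result list (q-values computed
    within each analysis across the motif family) and a motifs × analyses
    AUC table restricted to the *top* motifs ordered by their maximum AUC
    over the analyses, ties broken by motif id.
    """
    if scores.isna().any().any():
        raise ValueError("inconsistent universes: NaN scores across motifs")
    motif_ids = sorted(scores.index)
    child_seeds = np.random.SeedSequence(seed).spawn(len(gene_sets))

    results: list[EnrichmentResult] = []
    for gs, ss in zip(gene_sets, child_seeds):
        rng = np.random.default_rng(ss)
        rows = []
        for motif_id in motif_ids:
            auc, p = enrichment_test(scores.loc[motif_id], gs, n_perm=n_perm, rng=rng)
            rows.append((motif_id, auc, p))
        qs = bh_qvalues([p for _, _, p in rows])
        for (motif_id, auc, p), q in zip(rows, qs):
            results.append(
                EnrichmentResult(
                    motif_id=motif_id,
                    set_name=gs.name,
                    auc=auc,
                    p_value=p,
                    q_value=float(q),
                    tier=_tier(q, fdr, strict_fdr),
                )
            )

    frame = results_to_frame(results)
    auc_wide = frame.pivot(index="motif", columns="analysis", values="auc")
    auc_wide = auc_wide[[gs.name for gs in gene_sets]]
    order = sorted(auc_wide.index, key=lambda mid: (-auc_wide.loc[mid].max(), mid))
    heatmap = auc_wide.loc[order[:top]]
    return results, heatmap


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.set_name, r.motif_id, r.auc, r.p_value, r.q_value, r.tier) for r in results],
        columns=["analysis", "motif", "auc", "p", "q", "tier"],
    )


@dataclass
class OverlapSummary:
    """Which analyses each motif is significant in, plus intersections."""

    per_motif: dict[str, tuple[str, ...]]
    intersections: dict[tuple[str, ...], tuple[str, ...]]
    promoter_overlap: tuple[str, ...] | None = None

    def to_json_dict(self) -> dict:
        out = {
            "per_motif": {m: list(a) for m, a in self.per_motif.items()},
            "intersections": {" & ".join(k): list(v) for k, v in self.intersections.items()},
        }
        if self.promoter_overlap is not None:
            out["promoter_overlap"] = list(self.promoter_overlap)
        return out


def overlap_summary(
    results: Iterable[EnrichmentResult],
    promoter_motifs: Iterable[str] | None = None,
) -> OverlapSummary:
    """Cross-analysis overlap of significant motifs (tier ≠ none).

    For every combination of ≥2 analyses, lists the motifs significant in
    all of them; optionally intersects the union of significant motifs with
    an externally supplied promoter-hit motif list (e.g. a site scan of the
    promoter of interest).
    """
    results = list(results)
    analyses = sorted({r.set_name for r in results})
    if len(analyses) < 2:
        raise ValueError("overlap_summary needs results from at least 2 analyses")
    sig: dict[str, set[str]] = {}
    for r in results:
        if r.tier != TIER_NONE:
            sig.setdefault(r.motif_id, set()).add(r.set_name)
    per_motif = {m: tuple(sorted(a)) for m, a in sorted(sig.items())}
    intersections: dict[tuple[str, ...], tuple[str, ...]] = {}
    for r in range(2, len(analyses) + 1):
        for combo in itertools.combinations(analyses, r):
            hit = tuple(sorted(m for m, a in sig.items() if set(combo) <= a))
            intersections[combo] = hit
    promoter_overlap = None
    if promoter_motifs is not None:
        promoter_overlap = tuple(sorted(set(sig) & set(promoter_motifs)))
    return OverlapSummary(per_motif, intersections, promoter_overlap)
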