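"""Expression screening and co-expression gene-set construction.

The entry point of the pipeline: given a normalized probe-level expression
matrix from a two-condition design (e.g. dietary restriction vs. control),
screen a seed gene for significant induction, rank every other gene by its
Pearson correlation to the seed probe, and build top-N co-expression gene
sets — optionally restricted to an annotated subset such as nuclear-encoded
mitochondrial genes.  Probe handling follows Affymetrix conventions: probes
whose identifier carries a promiscuous ``_s_``/``_x_`` suffix are dropped
unless that would orphan their gene, and per-gene correlations are the
arithmetic mean over the gene's surviving probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_qvalues

__all__ = [
    "ExpressionMatrix",
    "InductionScreenResult",
    "GeneSet",
    "screen_induction",
    "filter_probes",
    "rank_correlations",
    "build_gene_set",
    "go_enrichment",
    "read_expression_tsv",
    "read_conditions_tsv",
    "read_probe_map_tsv",
    "read_gene_list",
    "read_go_annotation",
    "write_correlation_table",
    "write_gene_set",
]

#: substrings marking promiscuous / cross-hybridizing Affymetrix probes
DEFAULT_PROBE_SUFFIXES = ("_s_", "_x_")


@dataclass
class ExpressionMatrix:
    """Probe-level expression values with sample labels and probe→gene map.

    Parameters
    ----------
    values
        Probes × samples matrix of normalized log-scale intensities; the
        index holds probe identifiers, the columns sample identifiers.
    sample_conditions
        Condition label per sample (indexed by sample identifier).
    probe_to_gene
        Probe → gene-symbol map; probes absent from the map are unmapped.
    """

    values: pd.DataFrame
    sample_conditions: pd.Series
    probe_to_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicated probe ids: {dups[:5]}")
        missing = set(self.values.columns) - set(self.sample_conditions.index)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        self.sample_conditions = self.sample_conditions.loc[self.values.columns]

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    def condition_samples(self, label: str) -> list[str]:
        """Sample ids carrying a given condition label."""
        mask = self.sample_conditions == label
        return list(self.sample_conditions.index[mask])

    def probes_for_gene(self, gene: str) -> list[str]:
        present = set(self.values.index)
        return [p for p, g in self.probe_to_gene.items() if g == gene and p in present]


@dataclass(frozen=True)
class InductionScreenResult:
    """Two-sample t-test outcome for one probe of the screened gene."""

    probe_id: str
    group_means: dict[str, float]
    t_statistic: float
    p_value: float
    passes: bool


@dataclass(frozen=True)
class GeneSet:
    """A named top-N co-expression gene set anchored on a seed gene."""

    name: str
    seed_gene: str
    members: tuple[str, ...]
    track: str = "all"

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("gene set members must be unique")
        if self.seed_gene not in self.members:
            raise ValueError("seed gene must be a member of its own set")

    @property
    def size(self) -> int:
        return len(self.members)


def screen_induction(
    matrix: ExpressionMatrix,
    gene: str,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> list[InductionScreenResult]:
    """Test each probe of *gene* for a mean difference between two conditions.

    Classic pooled-variance two-sample Student t-test, two-tailed, applied to
    every probe of the gene individually.  ``passes`` is ``p < alpha``.

    Degenerate pooled variance is resolved by convention: equal group means
    give p = 1; unequal means with zero pooled variance give p = 0 (with a
    warning), since the separation is then infinitely many standard errors.
    """
    probes = matrix.probes_for_gene(gene)
    if not probes:
        raise KeyError(f"gene {gene!r} maps to no probe in the matrix")
    samples_a = matrix.condition_samples(group_a)
    samples_b = matrix.condition_samples(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs at least 2 samples for a t-test")

    results = []
    for probe in probes:
        a = matrix.values.loc[probe, samples_a].to_numpy(dtype=float)
        b = matrix.values.loc[probe, samples_b].to_numpy(dtype=float)
        pooled = a.var(ddof=1) + b.var(ddof=1)
        if pooled == 0.0:
            if a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                warnings.warn(
                    f"probe {probe}: zero pooled variance with unequal means; p=0 by convention"
                )
                t = np.inf if a.mean() > b.mean() else -np.inf
                p = 0.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        results.append(
            InductionScreenResult(
                probe_id=probe,
                group_means={group_a: float(a.mean()), group_b: float(b.mean())},
                t_statistic=float(t),
                p_value=float(p),
                passes=bool(p < alpha),
            )
        )
    return results


def filter_probes(
    matrix: ExpressionMatrix,
    suffixes: Sequence[str] = DEFAULT_PROBE_SUFFIXES,
) -> ExpressionMatrix:
    """Drop promiscuous-suffix probes without ever orphaning a gene.

    A probe whose identifier contains any of *suffixes* (anywhere) is
    removed, except when all of its gene's probes carry such suffixes — then
    the gene keeps all its probes.  Unmapped probes are retained unchanged.
    """

    def is_suffixed(probe: str) -> bool:
        return any(s in probe for s in suffixes)

    per_gene: dict[str, list[str]] = {}
    present = set(matrix.values.index)
    for probe, gene in matrix.probe_to_gene.items():
        if probe in present:
            per_gene.setdefault(gene, []).append(probe)

    keep: list[str] = []
    for probe in matrix.values.index:
        gene = matrix.probe_to_gene.get(probe)
        if gene is None or not is_suffixed(probe):
            keep.append(probe)
        elif all(is_suffixed(p) for p in per_gene[gene]):
            # removing this probe would leave the gene without any probe
            keep.append(probe)
    return ExpressionMatrix(
        values=matrix.values.loc[keep],
        sample_conditions=matrix.sample_conditions,
        probe_to_gene=dict(matrix.probe_to_gene),
    )


def rank_correlations(matrix: ExpressionMatrix, seed_probe: str) -> pd.DataFrame:
    """Rank genes by mean Pearson correlation of their probes to a seed probe.

    Returns a DataFrame indexed by gene with columns ``mean_r``,
    ``n_probes`` and ``rank`` (1 = most correlated), sorted by rank.  Genes
    with several probes get the arithmetic mean of their probes' r values.
    Zero-variance probes are excluded with a warning; a zero-variance seed
    probe is an error (Pearson r undefined).
    """
    if seed_probe not in matrix.values.index:
        raise KeyError(f"seed probe {seed_probe!r} not in matrix")
    if matrix.values.shape[1] < 3:
        raise ValueError("need at least 3 samples to rank correlations")

    X = matrix.values.to_numpy(dtype=float)
    seed = matrix.values.loc[seed_probe].to_numpy(dtype=float)
    seed_c = seed - seed.mean()
    seed_norm = np.sqrt((seed_c**2).sum())
    if seed_norm == 0:
        raise ValueError(f"seed probe {seed_probe!r} has zero variance")

    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    zero_var = norms == 0
    if zero_var.any():
        bad = matrix.values.index[zero_var].tolist()
        warnings.warn(f"excluding {len(bad)} zero-variance probe(s) from correlation: {bad[:5]}")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ seed_c) / (norms * seed_norm)

    rows = []
    for probe, ri, zv in zip(matrix.values.index, r, zero_var):
        gene = matrix.probe_to_gene.get(probe)
        if gene is None or zv:
            continue
        rows.append((gene, float(ri)))
    if not rows:
        raise ValueError("no mapped, non-degenerate probes to correlate")
    df = pd.DataFrame(rows, columns=["gene", "r"])
    table = df.groupby("gene").agg(mean_r=("r", "mean"), n_probes=("r", "size"))
    table = table.sort_values(["mean_r", "gene"], ascending=[False, True], kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def build_gene_set(
    table: pd.DataFrame,
    seed_gene: str,
    n: int,
    track: str = "all",
    mito_list: Iterable[str] | None = None,
    name: str | None = None,
) -> GeneSet:
    """Take the seed gene plus the (N−1) most seed-correlated eligible genes.

    The seed counts toward N.  For ``track="mitochondrial"`` eligibility is
    membership in *mito_list* (a curated mitochondrial-gene inventory such
    as MitoCarta).  Boundary ties in mean r are broken by lexicographic gene
    symbol, making the construction deterministic.
    """
    if n < 1:
        raise ValueError("gene set size must be >= 1")
    if track not in ("all", "mitochondrial"):
        raise ValueError(f"unknown track {track!r}")
    if track == "mitochondrial":
        if mito_list is None:
            raise ValueError("mitochondrial track requires a mitochondrial gene list")
        eligible_pool = set(mito_list)
    else:
        eligible_pool = None

    candidates = table.drop(index=seed_gene, errors="ignore")
    if eligible_pool is not None:
        candidates = candidates.loc[candidates.index.isin(eligible_pool)]
    if len(candidates) < n - 1:
        raise ValueError(
            f"only {len(candidates)} eligible genes for track {track!r}; "
            f"need {n - 1} besides the seed"
        )
    # descending r, boundary ties by gene symbol
    ordered = sorted(candidates.index, key=lambda g: (-candidates.loc[g, "mean_r"], g))
    members = (seed_gene, *ordered[: n - 1])
    return GeneSet(
        name=name or f"{seed_gene}_top{n}_{track}",
        seed_gene=seed_gene,
        members=members,
        track=track,
    )


def go_enrichment(
    gene_set: GeneSet | Sequence[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric term over-representation with Benjamini–Hochberg FDR.

    For every annotation term, p is the upper-tail hypergeometric
    probability of drawing at least the observed number of term genes when
    sampling ``|set|`` genes from the universe; q adjusts across all tested
    terms.  Returns a DataFrame (term, term_size, overlap, p_value, q_value)
    sorted by p.
    """
    members = set(gene_set.members if isinstance(gene_set, GeneSet) else gene_set)
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    if not members <= universe_set:
        raise ValueError("gene set must be a subset of the universe")

    term_genes: dict[str, set[str]] = {}
    for gene in universe_set:
        for term in annotation.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)

    M, n_draw = len(universe_set), len(members)
    rows = []
    for term, genes in sorted(term_genes.items()):
        K = len(genes)
        k = len(genes & members)
        p = float(stats.hypergeom.sf(k - 1, M, K, n_draw))
        rows.append((term, K, k, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p_value"])
    df["q_value"] = bh_qvalues(df["p_value"].to_numpy()) if len(df) else []
    return df.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O — tab-separated dialects, including the GEO series-matrix variant
# ---------------------------------------------------------------------------

def read_expression_tsv(path) -> pd.DataFrame:
    """Read a probe × sample TSV (first column probe id, header sample ids).

    Lines starting with ``!`` (GEO series-matrix metadata) are skipped, so a
    series-matrix file can be consumed directly.
    """
    df = pd.read_csv(path, sep="\t", comment="!", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [str(c).strip('"') for c in df.columns]
    return df


def read_conditions_tsv(path) -> pd.Series:
    """Two-column sample → condition TSV (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "condition"], dtype=str)
    return df.set_index("sample")["condition"]


def read_probe_map_tsv(path) -> dict[str, str]:
    """Two-column probe → gene TSV (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"], dtype=str)
    return dict(zip(df["probe"], df["gene"]))


def read_gene_list(path) -> list[str]:
    """One gene symbol per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_go_annotation(path) -> dict[str, set[str]]:
    """TSV ``gene<TAB>term``, multiple rows per gene."""
    out: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def write_correlation_table(table: pd.DataFrame, path) -> None:
    table.reset_index().rename(columns={"index": "gene"}).to_csv(path, sep="\t", index=False)


def write_gene_set(gene_set: GeneSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name={gene_set.name}\tseed={gene_set.seed_gene}\ttrack={gene_set.track}\n")
        for gene in gene_set.members:
            fh.write(gene + "\n")
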