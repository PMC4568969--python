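"""Formula-level reductions of the validation assays.

Two small, self-contained statistics used when following up a candidate
regulator at the bench: reference-gene relative expression from qPCR Ct
tables (ΔΔCt with amplification efficiency fixed at 2), and
background-normalized ChIP percent-input with replicate averaging.  Both
report two-tailed pooled-variance Student t-tests between conditions.
"""

from __future__ import annotations

import pandas as pd
import numpy as np
from scipy import stats

__all__ = ["relative_expression", "chip_normalize", "read_qpcr_tsv", "read_chip_tsv"]

QPCR_COLUMNS = ["sample", "condition", "gene", "ct"]
CHIP_COLUMNS = ["precipitation", "condition", "gene", "percent_input"]


def _student_t(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if a.var(ddof=1) + b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def relative_expression(
    table: pd.DataFrame,
    reference_gene: str,
    control_condition: str,
) -> pd.DataFrame:
    """Per-(gene, condition) fold change relative to a control condition.

    Long-format input with columns ``sample, condition, gene, ct``.  For
    each sample, ΔCt = Ct(gene) − Ct(reference gene); per condition the
    ΔCt values are averaged, ΔΔCt subtracts the control-condition mean, and
    fold = 2^(−ΔΔCt).  The reported p-value is a two-tailed Student t on the
    per-sample ΔCt values between the condition and the control.
    """
    df = table.copy()
    missing_cols = set(QPCR_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"Ct table missing columns: {sorted(missing_cols)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    ref = df[df["gene"] == reference_gene].set_index("sample")["ct"]
    samples = df["sample"].unique()
    without_ref = [s for s in samples if s not in ref.index]
    if without_ref:
        raise ValueError(f"samples missing reference-gene Ct: {without_ref[:5]}")
    if control_condition not in set(df["condition"]):
        raise ValueError(f"control condition {control_condition!r} absent from table")

    df = df[df["gene"] != reference_gene].copy()
    df["delta_ct"] = df["ct"] - df["sample"].map(ref).astype(float)

    rows = []
    for gene, sub in df.groupby("gene", sort=True):
        ctrl = sub.loc[sub["condition"] == control_condition, "delta_ct"].to_numpy()
        if ctrl.size == 0:
            raise ValueError(f"gene {gene}: no control-condition measurements")
        for condition, cond_sub in sub.groupby("condition", sort=True):
            d = cond_sub["delta_ct"].to_numpy()
            ddct = d.mean() - ctrl.mean()
            p = 1.0 if condition == control_condition else _student_t(d, ctrl)
            rows.append((gene, condition, len(d), float(2.0 ** (-ddct)), p))
    return pd.DataFrame(rows, columns=["gene", "condition", "n", "fold_change", "p_value"])


def chip_normalize(
    table: pd.DataFrame,
    background_gene: str,
    control_condition: str | None = None,
) -> pd.DataFrame:
    """Background-normalized ChIP percent input per target gene.

    Long-format input with columns ``precipitation, condition, gene,
    percent_input``.  Within each precipitation, every target's percent
    input is divided by the background gene's percent input (a locus not
    expected to be bound, e.g. β-actin); normalized values are then averaged
    across precipitations with a standard error (sd/√n).  When
    *control_condition* is given, each (gene, condition) is tested against
    the same gene's control values with a two-tailed Student t.
    """
    df = table.copy()
    missing_cols = set(CHIP_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"ChIP table missing columns: {sorted(missing_cols)}")
    if (df["percent_input"] < 0).any():
        raise ValueError("percent input must be nonnegative")

    bg = df[df["gene"] == background_gene].set_index(["precipitation", "condition"])["percent_input"]
    if bg.index.has_duplicates:
        raise ValueError("multiple background rows for one precipitation")
    df = df[df["gene"] != background_gene].copy()
    keys = pd.MultiIndex.from_frame(df[["precipitation", "condition"]])
    missing = keys.difference(bg.index)
    if len(missing):
        raise ValueError(f"precipitations without background gene: {list(missing)[:5]}")
    denom = bg.loc[keys].to_numpy(dtype=float)
    if (denom == 0).any():
        raise ValueError("zero background percent input")
    df["normalized"] = df["percent_input"].to_numpy(dtype=float) / denom

    grouped = {
        (gene, cond): sub["normalized"].to_numpy()
        for (gene, cond), sub in df.groupby(["gene", "condition"], sort=True)
    }
    rows = []
    for (gene, cond), vals in grouped.items():
        if vals.size < 2:
            raise ValueError(f"gene {gene}, condition {cond}: need >=2 precipitations for SE")
        se = float(vals.std(ddof=1) / np.sqrt(vals.size))
        p = float("nan")
        if control_condition is not None:
            ctrl = grouped.get((gene, control_condition))
            if ctrl is None:
                raise ValueError(f"gene {gene}: no control-condition precipitations")
            p = 1.0 if cond == control_condition else _student_t(vals, ctrl)
        rows.append((gene, cond, vals.size, float(vals.mean()), se, p))
    return pd.DataFrame(
        rows, columns=["gene", "condition", "n", "normalized_mean", "se", "p_value"]
    )


def read_qpcr_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str, "gene": str})


def read_chip_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"precipitation": str, "condition": str, "gene": str})
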