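"""Metabolome differential statistics and expression quantification.

Metabolome: two-group comparison of protein-normalized metabolite
abundances by Welch's unequal-variance t-test and group-mean fold changes,
summarized with the two significance thresholds (p <= 0.05 and
0.05 < p < 0.1) split by direction and grouped by pathway.

Expression: FPKM (fragments per kilobase of exon per million mapped
fragments) from count tables with gene lengths, and log2(FPKM + 1) tables
for cross-condition comparison.  No multiple-testing correction is applied
by default (raw Welch p-values with two thresholds are reported); a
Benjamini-Hochberg column is available on request.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaboliteAbundanceTable",
    "welch_test",
    "fold_change",
    "differential_metabolome",
    "summarize_significance",
    "compute_fpkm",
    "log2_expression_compare",
    "read_abundance_table",
]


@dataclass
class MetaboliteAbundanceTable:
    """Protein-normalized metabolite abundances for two sample groups.

    ``frame``: rows = metabolites, columns = super_pathway, sub_pathway and
    one column per sample.  ``groups``: sample column -> group label.
    """

    frame: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self):
        labels = set(self.groups.values())
        if len(labels) != 2:
            raise ValueError("exactly two groups are required")
        for g in labels:
            if sum(1 for v in self.groups.values() if v == g) < 2:
                raise ValueError(f"group {g} has fewer than 2 samples")
        sample_cols = self.sample_columns
        if (self.frame[sample_cols] < 0).any().any():
            raise ValueError("abundances must be >= 0")

    @property
    def sample_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c in self.groups]

    def group_values(self, metabolite: str, group: str) -> np.ndarray:
        cols = [c for c in self.sample_columns if self.groups[c] == group]
        return self.frame.loc[metabolite, cols].to_numpy(dtype=float)


def read_abundance_table(path, decimal: str = ".", sep: str = "\t") -> pd.DataFrame:
    """Read a metabolite table; ``decimal=","`` parses decimal-comma cells
    (the dialect of printed supplementary tables such as "38,76")."""
    return pd.read_csv(path, sep=sep, decimal=decimal)


# ---------------------------------------------------------------------------
# Welch's t-test and fold change
# ---------------------------------------------------------------------------

def welch_test(group1: Sequence[float], group2: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sample t-test: (t, Welch-Satterthwaite df, two-sided p).

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2).  Degenerate zero-variance
    inputs: equal means give (0, df, 1); different means give p -> 0.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    m1, m2 = a.mean(), b.mean()
    v1 = a.var(ddof=1)
    v2 = b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0
        return float(np.sign(m1 - m2) * np.inf), float(n1 + n2 - 2), 0.0
    t = (m1 - m2) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def fold_change(group1: Sequence[float], group2: Sequence[float]) -> float:
    """Ratio of group means, mean(group1) / mean(group2)."""
    m1 = float(np.mean(group1))
    m2 = float(np.mean(group2))
    if m2 == 0:
        return float("inf")
    return m1 / m2


def differential_metabolome(table: MetaboliteAbundanceTable,
                            group1: str, group2: str,
                            log_transform: bool = False,
                            bh_fdr: bool = False) -> pd.DataFrame:
    """Per-metabolite fold change (group1/group2) and Welch test.

    The test runs on raw abundances by default; ``log_transform`` tests
    log-scale values instead (fold changes stay on the raw scale).
    """
    rows = []
    for met in table.frame.index:
        a = table.group_values(met, group1)
        b = table.group_values(met, group2)
        fc = fold_change(a, b)
        if log_transform:
            a = np.log(np.maximum(a, 1e-12))
            b = np.log(np.maximum(b, 1e-12))
        t, df, p = welch_test(a, b)
        rows.append({
            "metabolite": met,
            "super_pathway": table.frame.loc[met].get("super_pathway", ""),
            "sub_pathway": table.frame.loc[met].get("sub_pathway", ""),
            "fold_change": fc, "t": t, "df": df, "p": p,
        })
    out = pd.DataFrame(rows).set_index("metabolite")
    if bh_fdr:
        from statsmodels.stats.multitest import multipletests
        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def summarize_significance(results: pd.DataFrame,
                           thresholds: tuple[float, float] = (0.05, 0.1)) -> dict:
    """Significance counts and pathway-grouped listing.

    Returns counts of metabolites with p <= thresholds[0] and with
    thresholds[0] < p < thresholds[1], each split by direction (fold
    change > 1 = up, < 1 = down), plus the significant rows grouped by
    super/sub pathway.
    """
    if results.empty:
        raise ValueError("no results to summarize")
    lo, hi = thresholds
    sig = results[results["p"] <= lo]
    trend = results[(results["p"] > lo) & (results["p"] < hi)]
    counts = {
        "n_significant": len(sig),
        "n_significant_up": int((sig["fold_change"] > 1).sum()),
        "n_significant_down": int((sig["fold_change"] < 1).sum()),
        "n_trend": len(trend),
        "n_trend_up": int((trend["fold_change"] > 1).sum()),
        "n_trend_down": int((trend["fold_change"] < 1).sum()),
    }
    grouped = (sig.sort_values(["super_pathway", "sub_pathway", "p"])
               .reset_index(names="metabolite")
               [["super_pathway", "sub_pathway", "metabolite",
                 "fold_change", "p"]])
    return {"counts": counts, "by_pathway": grouped}


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def compute_fpkm(records: pd.DataFrame,
                 totals: Optional[dict[str, float]] = None) -> pd.DataFrame:
    """FPKM per gene per sample: count * 1e9 / (length * total).

    ``records`` has columns gene, length and one count column per sample;
    ``totals`` (per-sample total mapped fragments) defaults to the column
    sums.
    """
    if (records["length"] <= 0).any():
        raise ValueError("gene lengths must be > 0")
    samples = [c for c in records.columns if c not in ("gene", "length")]
    out = records[["gene", "length"]].copy()
    for s in samples:
        total = totals[s] if totals is not None else float(records[s].sum())
        if total <= 0:
            raise ValueError(f"sample {s}: total mapped fragments must be > 0")
        out[s] = records[s].to_numpy(dtype=float) * 1e9 / (
            records["length"].to_numpy(dtype=float) * total)
    return out


def log2_expression_compare(fpkm: pd.DataFrame,
                            epsilon: float = 1.0) -> pd.DataFrame:
    """log2(FPKM + epsilon) per gene and condition, for grouped-bar export.

    The pseudocount applies to the displayed values only; raw FPKM stays
    unshifted elsewhere.
    """
    samples = [c for c in fpkm.columns if c not in ("gene", "length")]
    out = fpkm[["gene"]].copy()
    for s in samples:
        out[s] = np.log2(fpkm[s].to_numpy(dtype=float) + epsilon)
    return out
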